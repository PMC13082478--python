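"""Detection and overlap evaluation of a predicted lesion set against a
reference: one-to-one matching, size-stratified precision/sensitivity/F1,
and patient-wise Dice overlap."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from lesiontrack.lesions import Lesion
from lesiontrack.tracking import _assign
from lesiontrack.volumes import LabelVolume

STRATA = ("all", "ge5mm", "lt5mm")


class Counts(NamedTuple):
    tp: int
    fp: int
    fn: int


@dataclass
class DetectionResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]]  # (pred_id, ref_id)
    strata: dict[str, Counts]


@dataclass(frozen=True)
class DetectionMetrics:
    """precision = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 = harmonic
    mean; None when the denominator is zero."""

    precision: float | None
    sensitivity: float | None
    f1: float | None


@dataclass(frozen=True)
class OverlapResult:
    patient_id: str
    dsc: float


def _longest(lesion: Lesion) -> float:
    if lesion.dmax is None:
        raise ValueError("lesion diameters not computed; run measure_lesions before stratifying")
    return lesion.dmax.longest_mm


def match_detections(pred: list[Lesion], ref: list[Lesion], *,
                     size_threshold_mm: float = 5.0,
                     min_overlap_voxels: int = 1) -> DetectionResult:
    """Match predicted to reference lesions and count TP/FP/FN per stratum.

    A globally optimal one-to-one assignment maximizes total voxel
    overlap; a pair counts as a true positive only when the overlap is
    at least ``min_overlap_voxels`` (no Dice or distance threshold —
    the most permissive criterion).  TP/FN strata follow the REFERENCE
    lesion's longest diameter (inclusive at the threshold); false
    positives are stratified by their own longest diameter.
    """
    pairs_idx = [(i, j) for i, j in _assign(pred, ref, gate_mm=-1.0)
                 if pred[i].overlap_voxels(ref[j]) >= min_overlap_voxels]
    matched_pred = {i for i, _ in pairs_idx}
    matched_ref = {j for _, j in pairs_idx}

    strata = {s: [0, 0, 0] for s in STRATA}  # tp, fp, fn

    def stratum_of(lesion: Lesion) -> str:
        return "ge5mm" if _longest(lesion) >= size_threshold_mm else "lt5mm"

    for _, j in pairs_idx:
        for s in ("all", stratum_of(ref[j])):
            strata[s][0] += 1
    for i, lesion in enumerate(pred):
        if i not in matched_pred:
            for s in ("all", stratum_of(lesion)):
                strata[s][1] += 1
    for j, lesion in enumerate(ref):
        if j not in matched_ref:
            for s in ("all", stratum_of(lesion)):
                strata[s][2] += 1

    counts = {s: Counts(*v) for s, v in strata.items()}
    return DetectionResult(
        tp=counts["all"].tp, fp=counts["all"].fp, fn=counts["all"].fn,
        pairs=[(pred[i].lesion_id, ref[j].lesion_id) for i, j in pairs_idx],
        strata=counts,
    )


def detection_metrics(counts: tuple[int, int, int]) -> DetectionMetrics:
    """Precision/sensitivity/F1 from raw (tp, fp, fn) counts.

    Values are exact ratios; rounding happens only at presentation.
    """
    tp, fp, fn = (int(c) for c in counts)
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    if tp == 0 and fp == 0 and fn == 0:
        raise ValueError("all-zero counts: metrics undefined")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    f1 = None
    if precision is not None and sensitivity is not None and precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return DetectionMetrics(precision=precision, sensitivity=sensitivity, f1=f1)


def dice_patient(pred_volumes: list[LabelVolume], ref_volumes: list[LabelVolume],
                 patient_id: str = "", *, pooled: bool = True) -> OverlapResult:
    """Patient-wise Sorensen-Dice coefficient.

    All of the patient's studies are pooled before computing
    2|A∩B| / (|A|+|B|) (one number per patient).  With
    ``pooled=False`` the median of per-study DSCs is returned instead.
    Raises when both sides are empty (DSC undefined).
    """
    if len(pred_volumes) != len(ref_volumes) or not pred_volumes:
        raise ValueError("need one or more matched (pred, ref) volume pairs")
    inters, sizes_a, sizes_b, per_study = [], [], [], []
    for p, r in zip(pred_volumes, ref_volumes):
        if p.grid.shape != r.grid.shape:
            raise ValueError("pred/ref volume shapes differ; resample first")
        a = p.data > 0
        b = r.data > 0
        inter = int(np.count_nonzero(a & b))
        na, nb = int(a.sum()), int(b.sum())
        inters.append(inter)
        sizes_a.append(na)
        sizes_b.append(nb)
        if na + nb > 0:
            per_study.append(2 * inter / (na + nb))
    if sum(sizes_a) + sum(sizes_b) == 0:
        raise ValueError("both pooled masks empty: DSC undefined")
    if pooled:
        dsc = 2 * sum(inters) / (sum(sizes_a) + sum(sizes_b))
    else:
        dsc = float(np.median(per_study))
    return OverlapResult(patient_id=patient_id, dsc=float(dsc))


def dice_cohort(results: list[OverlapResult]) -> dict:
    """Cohort summary of per-patient DSC: median and IQR."""
    if not results:
        raise ValueError("no per-patient results")
    vals = np.array([r.dsc for r in results])
    q1, q3 = np.percentile(vals, [25, 75])
    return {"median": float(np.median(vals)), "iqr": (float(q1), float(q3)), "n": len(vals)}
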