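"""Paired-reader agreement: consensus construction, per-reader detection
metrics, ICC / Spearman / Bland-Altman statistics, and characterization
of lesions found by only one reader."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from lesiontrack.evaluation import DetectionMetrics, detection_metrics

CSV_COLUMNS = ["reader_id", "patient_id", "study_index", "lesion_ref", "longest_mm", "perpendicular_mm"]


@dataclass(frozen=True)
class ReaderMeasurement:
    """One reader's bidimensional measurement of one lesion at one study.

    ``lesion_ref`` keys the lesion to the reference standard; None marks
    a reader-only finding that cannot be keyed.
    """

    reader_id: str
    patient_id: str
    study_index: int
    lesion_ref: int | None
    longest_mm: float
    perpendicular_mm: float

    def __post_init__(self) -> None:
        if self.longest_mm < 0 or self.perpendicular_mm < 0:
            raise ValueError("diameters must be >= 0")

    @property
    def key(self) -> tuple:
        return (self.patient_id, self.study_index, self.lesion_ref)


@dataclass(frozen=True)
class AgreementStats:
    icc: float
    spearman_rho: float
    bland_altman: tuple[float, float, float]  # (mean_diff, loa_low, loa_high)
    n_pairs: int

    @property
    def mean_diff_mm(self) -> float:
        return self.bland_altman[0]


@dataclass
class DiscrepantLesion:
    """A lesion detected by exactly one reader, with its adjudicated
    diameter and (if follow-up exists) endpoint response label."""

    source: str  # "R1" or "R2"
    dmax_mm: float
    endpoint_label: str | None = None


@dataclass
class DiscrepancySummary:
    n_discrepant: int
    n_only_r1: int
    n_only_r2: int
    median_dmax_mm: float | None
    iqr_dmax_mm: tuple[float, float] | None
    endpoint_counts: dict[str, int] = field(default_factory=dict)
    pct_pd: float = 0.0


def build_consensus(r1: list[ReaderMeasurement], r2: list[ReaderMeasurement],
                    adjudication: list[ReaderMeasurement] | None = None) -> list[ReaderMeasurement]:
    """Construct the reference standard from two readers plus adjudication.

    Lesions found by both readers get averaged diameters.  Lesions found
    by only one reader are kept only when the adjudicator confirmed them
    (their entry exists in ``adjudication``), with the adjudicated
    diameters; otherwise they are excluded with a warning.  Un-keyed
    findings (``lesion_ref`` None) cannot be matched and are excluded.
    """
    adj_by_key = {m.key: m for m in (adjudication or []) if m.lesion_ref is not None}
    r1_by_key = {m.key: m for m in r1 if m.lesion_ref is not None}
    r2_by_key = {m.key: m for m in r2 if m.lesion_ref is not None}
    for m in list(r1) + list(r2):
        if m.lesion_ref is None:
            warnings.warn(f"un-keyed finding by {m.reader_id} ({m.patient_id}, study {m.study_index}) excluded from consensus")

    consensus: list[ReaderMeasurement] = []
    for key in sorted(set(r1_by_key) | set(r2_by_key), key=lambda k: (k[0], k[1], k[2])):
        a, b = r1_by_key.get(key), r2_by_key.get(key)
        if a is not None and b is not None:
            consensus.append(ReaderMeasurement(
                reader_id="consensus", patient_id=key[0], study_index=key[1], lesion_ref=key[2],
                longest_mm=(a.longest_mm + b.longest_mm) / 2.0,
                perpendicular_mm=(a.perpendicular_mm + b.perpendicular_mm) / 2.0))
        else:
            adj = adj_by_key.get(key)
            if adj is None:
                only = a if a is not None else b
                warnings.warn(f"single-reader lesion {key} by {only.reader_id} lacks adjudication; excluded")
                continue
            consensus.append(ReaderMeasurement(
                reader_id="consensus", patient_id=key[0], study_index=key[1], lesion_ref=key[2],
                longest_mm=adj.longest_mm, perpendicular_mm=adj.perpendicular_mm))
    return consensus


def reader_detection_metrics(reader: list[ReaderMeasurement],
                             consensus: list[ReaderMeasurement]) -> DetectionMetrics:
    """Per-reader detection metrics against the consensus reference,
    matched by reference-lesion key."""
    ref_keys = {m.key for m in consensus}
    reader_keys = {m.key for m in reader}
    tp = len(reader_keys & ref_keys)
    fp = len(reader_keys - ref_keys)
    fn = len(ref_keys - reader_keys)
    return detection_metrics((tp, fp, fn))


def _icc_anova(arr: np.ndarray, form: str) -> float:
    """ICC by two-way ANOVA decomposition; ``form`` in {'icc2', 'icc3'}.

    icc2 = two-way random effects, absolute agreement, single rater;
    icc3 = two-way mixed, consistency, single rater.
    """
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((arr - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0 and mse <= 0:
        raise ValueError("zero variance in both readers: ICC undefined")
    if form == "icc3":
        return (msr - mse) / (msr + (k - 1) * mse)
    if form == "icc2":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    raise ValueError(f"unknown ICC form {form!r}")


def paired_agreement(pairs, icc_form: str = "icc2") -> AgreementStats:
    """Agreement statistics for paired diameter measurements.

    ICC defaults to two-way random effects, absolute agreement, single
    measurement; Spearman uses average ranks for ties; Bland-Altman
    limits are mean difference ± 1.96·SD (no small-n bias correction).
    Lesions seen by only one reader must already be excluded.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (r1, r2) pairs")
    icc = _icc_anova(arr, icc_form)
    rho = float(stats.spearmanr(arr[:, 0], arr[:, 1]).statistic)
    diffs = arr[:, 0] - arr[:, 1]
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementStats(icc=float(icc), spearman_rho=rho,
                          bland_altman=(mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd),
                          n_pairs=len(arr))


def relative_difference_pct(r1_mm: float, r2_mm: float) -> float:
    """(r1 - r2) / mean(r1, r2) × 100."""
    mean = (r1_mm + r2_mm) / 2.0
    if mean <= 0:
        raise ValueError("relative difference undefined for nonpositive mean")
    return 100.0 * (r1_mm - r2_mm) / mean


def summarize_discrepant(lesions: list[DiscrepantLesion]) -> DiscrepancySummary:
    """Characterize lesions found by exactly one reader: counts per
    source, median/IQR of adjudicated diameter, endpoint response
    distribution, and the percentage progressing (PD)."""
    n_r1 = sum(1 for l in lesions if l.source == "R1")
    n_r2 = sum(1 for l in lesions if l.source == "R2")
    n = len(lesions)
    if n_r1 + n_r2 != n:
        raise ValueError("every discrepant lesion must have source 'R1' or 'R2'")
    if n == 0:
        return DiscrepancySummary(0, 0, 0, None, None, {}, 0.0)
    dmaxes = np.array([l.dmax_mm for l in lesions], dtype=float)
    q1, q3 = np.percentile(dmaxes, [25, 75])
    counts: dict[str, int] = {}
    for l in lesions:
        if l.endpoint_label is not None:
            counts[l.endpoint_label] = counts.get(l.endpoint_label, 0) + 1
    pct_pd = 100.0 * counts.get("PD", 0) / n
    return DiscrepancySummary(n_discrepant=n, n_only_r1=n_r1, n_only_r2=n_r2,
                              median_dmax_mm=float(np.median(dmaxes)),
                              iqr_dmax_mm=(float(q1), float(q3)),
                              endpoint_counts=counts, pct_pd=pct_pd)


def read_measurements_csv(path: str | Path) -> list[ReaderMeasurement]:
    """Load reader measurements from CSV (columns as in ``CSV_COLUMNS``)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        ref = row.lesion_ref
        ref = None if pd.isna(ref) else int(ref)
        out.append(ReaderMeasurement(reader_id=str(row.reader_id), patient_id=str(row.patient_id),
                                     study_index=int(row.study_index), lesion_ref=ref,
                                     longest_mm=float(row.longest_mm),
                                     perpendicular_mm=float(row.perpendicular_mm)))
    return out


def write_measurements_csv(measurements: list[ReaderMeasurement], path: str | Path) -> Path:
    df = pd.DataFrame([{c: getattr(m, c) for c in CSV_COLUMNS} for m in measurements])
    df.to_csv(path, index=False)
    return Path(path)
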