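"""Per-lesion treatment response classification.

The rules collapse target-lesion response criteria onto a single lesion:
progression (PD) is judged against the NADIR (smallest diameter seen so
far), partial response (PR) against the BASELINE (diameter at first
presence), complete response (CR) requires absence, everything else is
stable (SD).  No absolute-mm minimum change is imposed, because
sub-5 mm lesions are explicitly in scope; thresholds are configurable.
CR is reversible: a lesion reappearing after CR is progression.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

from lesiontrack.tracking import LesionTrack, percent_change

CR = "CR"
PR = "PR"
SD = "SD"
PD = "PD"
NEW = "NEW"
NA = "NA"


@dataclass(frozen=True)
class ResponseConfig:
    """Thresholds for per-lesion response labels (percent change)."""

    pd_threshold_pct: float = 20.0
    pr_threshold_pct: float = -30.0
    endpoint_months: float = 12.0

    def __post_init__(self) -> None:
        if not (self.pd_threshold_pct > 0 > self.pr_threshold_pct):
            raise ValueError("require pd_threshold_pct > 0 > pr_threshold_pct")


@dataclass(frozen=True)
class ResponseLabel:
    study_index: int
    label: str
    basis_pct_from_baseline: float | None = None
    basis_pct_from_nadir: float | None = None


def classify_track(track: LesionTrack, cfg: ResponseConfig = ResponseConfig()) -> list[ResponseLabel]:
    """Label every measured timepoint of a track.

    The first measurement gets NA (track present from study 0) or NEW
    (track first appearing later).  For each following timepoint t:
    PD if the change from nadir exceeds ``pd_threshold_pct``; else CR if
    the lesion is absent; else PR if the change from baseline is at or
    below ``pr_threshold_pct``; else SD.  Reappearance after CR is PD.
    The result is also stored on ``track.response``.
    """
    if not track.measurements:
        raise ValueError("empty track")

    labels: list[ResponseLabel] = []
    baseline: float | None = None
    nadir: float | None = None
    in_cr = False

    for i, m in enumerate(track.measurements):
        present = m.present and m.longest_mm is not None and m.longest_mm > 0
        d = float(m.longest_mm) if present else 0.0

        if i == 0:
            if not present:
                raise ValueError("track's first measurement must be a present lesion with a diameter")
            baseline = nadir = d
            labels.append(ResponseLabel(m.study_index, NA if track.first_seen == 0 else NEW))
            continue

        pct_base = percent_change(d, baseline) if baseline and baseline > 0 else None
        pct_nadir = percent_change(d, nadir) if nadir and nadir > 0 else None

        if not present:
            label = CR
            in_cr = True
        elif in_cr:
            label = PD  # reappearance after complete response
        elif pct_nadir is not None and pct_nadir > cfg.pd_threshold_pct:
            label = PD
        elif pct_base is not None and pct_base <= cfg.pr_threshold_pct:
            label = PR
        else:
            label = SD

        labels.append(ResponseLabel(m.study_index, label, pct_base, pct_nadir))
        if present:
            nadir = d if nadir is None else min(nadir, d)

    track.response = labels
    return labels


def _endpoint_cutoff(first_date: datetime.date, months: float) -> datetime.date:
    return first_date + datetime.timedelta(days=months * 365.25 / 12.0)


def endpoint_response(track: LesionTrack, cfg: ResponseConfig,
                      study_dates: list[datetime.date]) -> ResponseLabel:
    """Response label at the observation endpoint.

    The endpoint is the latest study no later than ``endpoint_months``
    after the first study (or the last available study when follow-up is
    shorter — that study is then the latest one within the window).
    Returns NA when nothing beyond the track's baseline falls inside the
    window.
    """
    max_idx = max(m.study_index for m in track.measurements)
    if len(study_dates) <= max_idx:
        raise ValueError("study_dates shorter than the track's study indices")
    if list(study_dates) != sorted(study_dates):
        raise ValueError("study_dates must be ordered")

    labels = track.response or classify_track(track, cfg)
    cutoff = _endpoint_cutoff(study_dates[0], cfg.endpoint_months)
    eligible_idx = [i for i, date in enumerate(study_dates) if date <= cutoff]
    if not eligible_idx:
        return ResponseLabel(track.first_seen, NA)
    horizon = max(eligible_idx)
    in_window = [lab for lab in labels if lab.study_index <= horizon]
    if len(in_window) <= 1:  # nothing besides the track's baseline
        return ResponseLabel(track.first_seen, NA)
    return in_window[-1]
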