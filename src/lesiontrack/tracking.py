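"""Longitudinal lesion matching and track construction.

Lesions of consecutive studies are paired by a globally optimal
one-to-one assignment maximizing total voxel overlap (masks are assumed
co-registered, so overlap dominates).  Pairs with zero overlap are
admitted only when lesion centroids lie within a configurable gate,
which rescues small lesions whose registered footprints barely miss.
Ties are broken by smaller centroid distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from lesiontrack.lesions import Lesion


@dataclass
class Matching:
    """One-to-one correspondence between two lesion sets (by lesion id)."""

    pairs: list[tuple[int, int]]
    unmatched_prev: list[int]
    unmatched_curr: list[int]


@dataclass
class TrackMeasurement:
    """A track's state at one study; ``lesion_id`` None means absent."""

    study_index: int
    lesion_id: int | None
    longest_mm: float | None = None
    perpendicular_mm: float | None = None
    pct_change_long: float | None = None
    pct_change_perp: float | None = None

    @property
    def present(self) -> bool:
        return self.lesion_id is not None


@dataclass
class LesionTrack:
    """One anatomic lesion followed across studies."""

    track_id: int
    patient_id: str
    measurements: list[TrackMeasurement]
    first_seen: int
    response: list = field(default_factory=list)


def percent_change(curr_mm: float, prior_mm: float) -> float:
    """100 * (curr - prior) / prior; undefined for nonpositive prior."""
    if prior_mm <= 0:
        raise ValueError("percent change undefined for prior <= 0")
    return 100.0 * (curr_mm - prior_mm) / prior_mm


def _assign(prev: list[Lesion], curr: list[Lesion], gate_mm: float) -> list[tuple[int, int]]:
    """Optimal assignment on list indices; returns admissible (i, j) pairs."""
    n, m = len(prev), len(curr)
    if n == 0 or m == 0:
        return []
    overlap = np.zeros((n, m))
    dist = np.zeros((n, m))
    for i, a in enumerate(prev):
        for j, b in enumerate(curr):
            overlap[i, j] = a.overlap_voxels(b)
            dist[i, j] = np.linalg.norm(a.centroid_mm - b.centroid_mm)
    allowed = (overlap > 0) | (dist <= gate_mm)
    # overlap counts are integers, so tie-break terms must sum below 0.5
    norm = (dist.max() + 1.0) * 2.0 * (n + m + 1)
    # forbidden pairs must cost more than any achievable overlap rearrangement
    forbid = overlap.sum() + 2.0
    cost = -overlap + dist / norm
    cost[~allowed] = forbid
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if allowed[i, j]]


def match_lesions(prev: list[Lesion], curr: list[Lesion], gate_mm: float = 10.0) -> Matching:
    """Match two lesion sets one-to-one, maximizing total voxel overlap.

    Both sets must come from volumes resampled to a common grid.
    Leftover lesions on either side are reported unmatched.
    """
    pairs_idx = _assign(prev, curr, gate_mm)
    matched_prev = {i for i, _ in pairs_idx}
    matched_curr = {j for _, j in pairs_idx}
    return Matching(
        pairs=[(prev[i].lesion_id, curr[j].lesion_id) for i, j in pairs_idx],
        unmatched_prev=[l.lesion_id for k, l in enumerate(prev) if k not in matched_prev],
        unmatched_curr=[l.lesion_id for k, l in enumerate(curr) if k not in matched_curr],
    )


class _OpenTrack:
    __slots__ = ("footprint", "measurements", "first_seen", "first_volume")

    def __init__(self, lesion: Lesion, study_index: int):
        self.footprint = lesion
        self.first_seen = study_index
        self.first_volume = lesion.volume_mm3
        self.measurements = [_measurement_from_lesion(study_index, lesion)]


def _measurement_from_lesion(study_index: int, lesion: Lesion) -> TrackMeasurement:
    longest = perp = None
    if lesion.dmax is not None:
        longest = lesion.dmax.longest_mm
        perp = lesion.dmax.perpendicular_mm
    return TrackMeasurement(study_index=study_index, lesion_id=lesion.lesion_id,
                            longest_mm=longest, perpendicular_mm=perp)


def build_tracks(series: list[tuple[int, list[Lesion]]], gate_mm: float = 10.0,
                 patient_id: str = "") -> list[LesionTrack]:
    """Chain lesion matchings across chronologically ordered studies.

    A lesion unmatched in the current study opens a new track; a track
    with no match records an absent measurement and stays eligible to
    re-match at later studies via its last non-absent footprint (so a
    lesion that shrinks below resolution and regrows is reconnected).
    Track ids are assigned by (first_seen, descending first volume).
    """
    if not series:
        raise ValueError("series must contain at least one study")
    indices = [idx for idx, _ in series]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate study_index in series")
    if indices != sorted(indices):
        raise ValueError("study indices must be strictly increasing")

    first_idx, first_lesions = series[0]
    tracks = [_OpenTrack(l, first_idx) for l in first_lesions]

    for study_index, lesions in series[1:]:
        footprints = [t.footprint for t in tracks]
        pairs = _assign(footprints, lesions, gate_mm)
        matched_t = {i: j for i, j in pairs}
        matched_l = {j for _, j in pairs}
        for ti, track in enumerate(tracks):
            if ti in matched_t:
                lesion = lesions[matched_t[ti]]
                track.measurements.append(_measurement_from_lesion(study_index, lesion))
                track.footprint = lesion
            else:
                track.measurements.append(TrackMeasurement(study_index=study_index, lesion_id=None))
        for j, lesion in enumerate(lesions):
            if j not in matched_l:
                tracks.append(_OpenTrack(lesion, study_index))

    tracks.sort(key=lambda t: (t.first_seen, -t.first_volume))
    out = []
    for track_id, t in enumerate(tracks, start=1):
        _fill_percent_changes(t.measurements)
        out.append(LesionTrack(track_id=track_id, patient_id=patient_id,
                               measurements=t.measurements, first_seen=t.first_seen))
    return out


def _fill_percent_changes(measurements: list[TrackMeasurement]) -> None:
    """Percent change of each diameter vs the immediately prior study's
    measurement; None at first appearance or when the prior is absent
    or zero."""
    for prior, curr in zip(measurements, measurements[1:]):
        if not curr.present:
            continue
        if prior.present and prior.longest_mm and prior.longest_mm > 0 and curr.longest_mm is not None:
            curr.pct_change_long = percent_change(curr.longest_mm, prior.longest_mm)
        if prior.present and prior.perpendicular_mm and prior.perpendicular_mm > 0 and curr.perpendicular_mm is not None:
            curr.pct_change_perp = percent_change(curr.perpendicular_mm, prior.perpendicular_mm)
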