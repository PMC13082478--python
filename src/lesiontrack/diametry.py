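"""Axial orthogonal maximum diameters of a lesion (bidimensional measurement).

Conventions (all deliberate, for reproducibility):

* distances are between voxel CENTERS, so a single-voxel lesion measures
  0 mm in both directions;
* the longest diameter is the maximum pairwise center distance within one
  axial slice, maximized over all slices the lesion intersects (ties go
  to the lowest slice index);
* the perpendicular diameter is the caliper width of the same slice's
  voxel centers along the in-plane direction orthogonal to the longest
  segment (projection extent), which is always defined on a discrete grid;
* through-plane extent never enters the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from lesiontrack.lesions import Lesion
from lesiontrack.volumes import ImageGrid


@dataclass(frozen=True)
class DiameterPair:
    """Longest axial diameter and its orthogonal caliper width, in mm.

    ``endpoints_long`` are the two voxel centers (x, y in mm) realizing
    the longest diameter; ``endpoints_perp`` are the cross-section
    points realizing the extremes of the orthogonal projection.
    """

    longest_mm: float
    perpendicular_mm: float
    slice_index: int | None
    endpoints_long: tuple[tuple[float, float], tuple[float, float]]
    endpoints_perp: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        if self.perpendicular_mm > self.longest_mm + 1e-9:
            raise ValueError("perpendicular diameter exceeds longest diameter")


def _candidate_points(pts_mm: np.ndarray) -> np.ndarray:
    """Points that can realize the diameter: convex hull vertices when a
    hull exists, otherwise (degenerate/collinear sets) all points."""
    if len(pts_mm) <= 3:
        return pts_mm
    try:
        hull = ConvexHull(pts_mm)
    except QhullError:
        return pts_mm
    return pts_mm[hull.vertices]


def _longest_pair(pts_mm: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Max pairwise distance with deterministic (lexicographic) tie-break."""
    cand = _candidate_points(pts_mm)
    diff = cand[:, None, :] - cand[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    best = float(d2.max())
    tol = 1e-9 * max(best, 1.0)
    ii, jj = np.nonzero(d2 >= best - tol)
    pairs = []
    for i, j in zip(ii.tolist(), jj.tolist()):
        if i >= j:
            continue
        p, q = tuple(cand[i]), tuple(cand[j])
        pairs.append(min((p, q), (q, p)))
    p, q = min(pairs)
    return float(np.sqrt(best)), np.asarray(p), np.asarray(q)


def slice_diameters(cross_section, in_plane_spacing: tuple[float, float] = (1.0, 1.0)) -> DiameterPair:
    """Measure the orthogonal diameter pair of one axial cross-section.

    Parameters
    ----------
    cross_section
        Iterable of (x, y) voxel indices (or an (N, 2) array).
    in_plane_spacing
        mm per voxel along x and y; anisotropy is honored.

    Returns
    -------
    DiameterPair
        With ``slice_index`` unset (None); :func:`dmax` fills it in.
    """
    pts_vox = np.asarray(sorted(map(tuple, cross_section)) if not isinstance(cross_section, np.ndarray)
                         else sorted(map(tuple, cross_section.tolist())), dtype=float)
    if pts_vox.size == 0:
        raise ValueError("cross_section is empty")
    pts_vox = pts_vox.reshape(-1, 2)
    spacing = np.asarray(in_plane_spacing, dtype=float)
    pts_mm = pts_vox * spacing

    if len(pts_mm) == 1:
        pt = (float(pts_mm[0, 0]), float(pts_mm[0, 1]))
        return DiameterPair(0.0, 0.0, None, (pt, pt), (pt, pt))

    longest, p, q = _longest_pair(pts_mm)
    if longest == 0.0:
        pt = (float(p[0]), float(p[1]))
        return DiameterPair(0.0, 0.0, None, (pt, pt), (pt, pt))
    u = (q - p) / longest
    v = np.array([-u[1], u[0]])
    proj = pts_mm @ v
    lo, hi = int(np.argmin(proj)), int(np.argmax(proj))
    perpendicular = min(float(proj[hi] - proj[lo]), longest)  # guard float round-off
    return DiameterPair(
        longest_mm=longest,
        perpendicular_mm=perpendicular,
        slice_index=None,
        endpoints_long=((float(p[0]), float(p[1])), (float(q[0]), float(q[1]))),
        endpoints_perp=((float(pts_mm[lo, 0]), float(pts_mm[lo, 1])),
                        (float(pts_mm[hi, 0]), float(pts_mm[hi, 1]))),
    )


def dmax(lesion: Lesion, grid: ImageGrid) -> DiameterPair:
    """Maximum orthogonal diameter pair of a lesion in the axial plane.

    Every axial slice intersecting the lesion is measured; the returned
    pair comes from the slice maximizing the longest diameter, ties
    broken by lowest slice index.
    """
    voxels = lesion.voxels
    spacing = grid.in_plane_spacing
    best: DiameterPair | None = None
    for z in sorted(np.unique(voxels[:, 2]).tolist()):
        xy = voxels[voxels[:, 2] == z][:, :2]
        pair = slice_diameters(xy, spacing)
        if best is None or pair.longest_mm > best.longest_mm + 1e-12:
            best = DiameterPair(pair.longest_mm, pair.perpendicular_mm, int(z),
                                pair.endpoints_long, pair.endpoints_perp)
    assert best is not None
    return best


def measure_lesions(lesions: list[Lesion], grid: ImageGrid) -> list[Lesion]:
    """Fill ``dmax`` on each lesion in place; returns the same list."""
    for lesion in lesions:
        lesion.dmax = dmax(lesion, grid)
    return lesions
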