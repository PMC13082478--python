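"""Connected-component decomposition of label volumes into lesions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from lesiontrack.volumes import ImageGrid, LabelVolume

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class Lesion:
    """One connected foreground component at one timepoint.

    ``voxels`` is an (N, 3) array of (x, y, z) indices; ``dmax`` is
    filled by :func:`lesiontrack.diametry.measure_lesions`.
    """

    lesion_id: int
    study_index: int
    voxels: np.ndarray
    centroid_mm: np.ndarray
    volume_mm3: float
    dmax: "object | None" = None
    _voxel_set: frozenset | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.int64)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3 or len(self.voxels) == 0:
            raise ValueError("voxels must be a non-empty (N, 3) index array")
        self.centroid_mm = np.asarray(self.centroid_mm, dtype=float)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def voxel_set(self) -> frozenset:
        if self._voxel_set is None:
            self._voxel_set = frozenset(map(tuple, self.voxels.tolist()))
        return self._voxel_set

    def overlap_voxels(self, other: "Lesion") -> int:
        """Number of voxel indices shared with another lesion."""
        a, b = self.voxel_set, other.voxel_set
        if len(a) > len(b):
            a, b = b, a
        return len(a & b)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary structuring element for 6/18/26 adjacency."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def extract_lesions(vol: LabelVolume, connectivity: int = 26, min_voxels: int = 1) -> list[Lesion]:
    """Split a label volume into anatomically distinct lesions.

    Input labels are flattened to binary before componentization (the
    mask represents a single tissue class), so the result is invariant
    to any permutation of nonzero input labels.  Lesions are ordered by
    descending volume, ties broken by lowest centroid (z, y, x), and
    assigned ids 1..N in that order.

    Parameters
    ----------
    vol
        The label volume to decompose.
    connectivity
        Voxel adjacency: 6 (faces), 18 (+edges) or 26 (+corners).
    min_voxels
        Components smaller than this are dropped (default keeps all;
        sub-5 mm lesions are deliberately in scope).
    """
    structure = connectivity_structure(connectivity)
    labeled, n = ndimage.label(vol.data > 0, structure=structure)
    if n == 0:
        return []
    vox_per_mm3 = vol.grid.voxel_volume_mm3
    raw: list[tuple[float, tuple[float, float, float], np.ndarray]] = []
    for comp in range(1, n + 1):
        idx = np.argwhere(labeled == comp)
        if len(idx) < min_voxels:
            continue
        centroid_vox = idx.mean(axis=0)
        sort_key = (float(centroid_vox[2]), float(centroid_vox[1]), float(centroid_vox[0]))
        raw.append((len(idx) * vox_per_mm3, sort_key, idx))
    raw.sort(key=lambda item: (-item[0], item[1]))
    lesions = []
    for lesion_id, (volume, _, idx) in enumerate(raw, start=1):
        centroid_mm = vol.grid.voxel_to_mm(idx.mean(axis=0))[0]
        lesions.append(Lesion(lesion_id=lesion_id, study_index=vol.study_index,
                              voxels=idx, centroid_mm=centroid_mm, volume_mm3=volume))
    return lesions


def lesion_size_class(lesion: Lesion, threshold_mm: float = 5.0) -> str:
    """Classify a lesion as ``"measurable"`` (longest axial diameter >=
    threshold, inclusive) or ``"small"``.  Requires ``dmax``."""
    if lesion.dmax is None:
        raise ValueError(f"lesion {lesion.lesion_id}: dmax not computed; run measure_lesions first")
    return "measurable" if lesion.dmax.longest_mm >= threshold_mm else "small"
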