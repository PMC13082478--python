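import numpy as np
import pytest

from lesiontrack.volumes import ImageGrid, LabelVolume


@pytest.fixture
def unit_grid():
    return ImageGrid.from_spacing((32, 32, 16))


def make_volume(data, spacing=(1.0, 1.0, 1.0), study_index=0, patient_id=""):
    data = np.asarray(data, dtype=np.int32)
    grid = ImageGrid.from_spacing(data.shape, spacing)
    return LabelVolume(grid=grid, data=data, study_index=study_index, patient_id=patient_id)


def sphere_mask(shape, center, radius_vox):
    """Voxel centers within radius of center (digital sphere)."""
    idx = np.indices(shape, dtype=float)
    dist2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return (dist2 <= radius_vox**2).astype(np.int32)


def random_blob_2d(rng, max_voxels=500):
    """Connected-ish random 2D voxel set grown from a seed point."""
    n = int(rng.integers(1, max_voxels + 1))
    pts = {(0, 0)}
    frontier = [(0, 0)]
    while len(pts) < n:
        x, y = frontier[int(rng.integers(len(frontier)))]
        step = [(1, 0), (-1, 0), (0, 1), (0, -1)][int(rng.integers(4))]
        cand = (x + step[0], y + step[1])
        if cand not in pts:
            pts.add(cand)
            frontier.append(cand)
    return np.array(sorted(pts))


def brute_force_longest(pts_mm):
    """O(n^2) pairwise-distance oracle for the longest in-plane diameter."""
    pts = np.asarray(pts_mm, dtype=float)
    if len(pts) == 1:
        return 0.0
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1).max()))
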