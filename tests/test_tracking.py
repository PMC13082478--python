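import itertools

import numpy as np
import pytest

from lesiontrack.diametry import measure_lesions
from lesiontrack.lesions import extract_lesions
from lesiontrack.phantom import PhantomConfig, Trajectory, generate_phantom
from lesiontrack.tracking import build_tracks, match_lesions, percent_change

from conftest import make_volume


def lesions_from_cubes(cubes, shape=(40, 40, 16), study_index=0):
    """Render axis-aligned cubes [(x0, y0, z0, side), ...] and extract."""
    data = np.zeros(shape, dtype=np.int32)
    for x0, y0, z0, side in cubes:
        data[x0 : x0 + side, y0 : y0 + side, z0 : z0 + side] = 1
    vol = make_volume(data, study_index=study_index)
    return measure_lesions(extract_lesions(vol), vol.grid)


def oracle_best_assignment(prev, curr, gate_mm=10.0):
    """Exhaustive assignment oracle: max total overlap over all injective
    mappings, admitting zero-overlap pairs only within the gate."""
    n, m = len(prev), len(curr)
    best = -1.0
    k = min(n, m)
    for prev_subset in itertools.permutations(range(n), k):
        for curr_subset in itertools.permutations(range(m), k):
            total = 0
            for i, j in zip(prev_subset, curr_subset):
                ov = prev[i].overlap_voxels(curr[j])
                dist = np.linalg.norm(prev[i].centroid_mm - curr[j].centroid_mm)
                if ov == 0 and dist > gate_mm:
                    continue  # inadmissible pair: leave both unmatched
                total += ov
            best = max(best, total)
    return best


class TestPercentChange:
    @pytest.mark.parametrize("curr,prior,expected", [(12, 10, 20.0), (10, 10, 0.0), (7, 10, -30.0)])
    def test_arithmetic(self, curr, prior, expected):
        assert percent_change(curr, prior) == pytest.approx(expected)

    def test_nonpositive_prior_raises(self):
        with pytest.raises(ValueError):
            percent_change(5.0, 0.0)


class TestMatchLesions:
    def test_identity(self):
        lesions = lesions_from_cubes([(2, 2, 2, 4), (20, 20, 4, 3)])
        m = match_lesions(lesions, lesions)
        assert sorted(m.pairs) == [(1, 1), (2, 2)]
        assert m.unmatched_prev == [] and m.unmatched_curr == []

    def test_disappearing_lesion(self):
        prev = lesions_from_cubes([(2, 2, 2, 4)])
        m = match_lesions(prev, [])
        assert m.pairs == [] and m.unmatched_prev == [1] and m.unmatched_curr == []

    def test_matching_follows_space_not_list_order(self):
        # two stationary lesions whose ids swap between studies (sizes swap rank)
        prev = lesions_from_cubes([(2, 2, 2, 5), (25, 25, 4, 3)])
        curr = lesions_from_cubes([(2, 2, 2, 3), (25, 25, 4, 5)])
        # prev: id1 at (2,2,2) big; curr: id1 now the other location
        m = match_lesions(prev, curr)
        pair_map = dict(m.pairs)
        prev_by_id = {l.lesion_id: l for l in prev}
        curr_by_id = {l.lesion_id: l for l in curr}
        for pid, cid in pair_map.items():
            assert np.linalg.norm(prev_by_id[pid].centroid_mm - curr_by_id[cid].centroid_mm) < 3.0

    def test_gate_blocks_distant_zero_overlap(self):
        prev = lesions_from_cubes([(2, 2, 2, 3)])
        curr = lesions_from_cubes([(30, 30, 10, 3)])  # ~40 mm away, no overlap
        m = match_lesions(prev, curr, gate_mm=10.0)
        assert m.pairs == []
        m2 = match_lesions(prev, curr, gate_mm=100.0)
        assert m2.pairs == [(1, 1)]

    def test_exhaustive_assignment_oracle_random(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n, m = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            prev = lesions_from_cubes(
                [(int(rng.integers(1, 33)), int(rng.integers(1, 33)), int(rng.integers(1, 10)), int(rng.integers(2, 5)))
                 for _ in range(n)])
            curr = lesions_from_cubes(
                [(int(rng.integers(1, 33)), int(rng.integers(1, 33)), int(rng.integers(1, 10)), int(rng.integers(2, 5)))
                 for _ in range(m)])
            got = match_lesions(prev, curr)
            prev_by_id = {l.lesion_id: l for l in prev}
            curr_by_id = {l.lesion_id: l for l in curr}
            total = sum(prev_by_id[a].overlap_voxels(curr_by_id[b]) for a, b in got.pairs)
            assert total == oracle_best_assignment(prev, curr)


class TestBuildTracks:
    def test_stationary_lesion_three_studies(self):
        series = [(t, lesions_from_cubes([(5, 5, 5, 4)], study_index=t)) for t in range(3)]
        tracks = build_tracks(series)
        assert len(tracks) == 1
        assert all(m.present for m in tracks[0].measurements)
        assert [m.study_index for m in tracks[0].measurements] == [0, 1, 2]

    def test_vanishing_lesion_records_absence(self):
        series = [
            (0, lesions_from_cubes([(5, 5, 5, 4)])),
            (1, lesions_from_cubes([(5, 5, 5, 4)])),
            (2, []),
        ]
        tracks = build_tracks(series)
        assert len(tracks) == 1
        assert tracks[0].measurements[2].lesion_id is None

    def test_new_lesion_opens_track(self):
        series = [
            (0, lesions_from_cubes([(5, 5, 5, 4)])),
            (1, lesions_from_cubes([(5, 5, 5, 4), (25, 25, 4, 3)])),
        ]
        tracks = build_tracks(series)
        assert len(tracks) == 2
        assert tracks[1].first_seen == 1
        assert [m.study_index for m in tracks[1].measurements] == [1]

    def test_rematch_after_gap_uses_last_footprint(self):
        series = [
            (0, lesions_from_cubes([(5, 5, 5, 4)])),
            (1, []),
            (2, lesions_from_cubes([(5, 5, 5, 4)])),
        ]
        tracks = build_tracks(series)
        assert len(tracks) == 1
        present = [m.present for m in tracks[0].measurements]
        assert present == [True, False, True]

    def test_duplicate_study_index_rejected(self):
        lesions = lesions_from_cubes([(5, 5, 5, 4)])
        with pytest.raises(ValueError, match="duplicate"):
            build_tracks([(0, lesions), (0, lesions)])

    def test_percent_changes_vs_prior(self):
        series = [
            (0, lesions_from_cubes([(5, 5, 5, 6)])),   # centers span 5 mm in-plane... diag
            (1, lesions_from_cubes([(5, 5, 5, 11)])),
        ]
        tracks = build_tracks(series)
        m0, m1 = tracks[0].measurements
        assert m0.pct_change_long is None
        assert m1.pct_change_long == pytest.approx(percent_change(m1.longest_mm, m0.longest_mm))

    def test_conservation_of_measurements(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            series = []
            total = 0
            for t in range(4):
                cubes = [(int(rng.integers(1, 30)), int(rng.integers(1, 30)), int(rng.integers(1, 10)), 3)
                         for _ in range(int(rng.integers(0, 4)))]
                lesions = lesions_from_cubes(cubes, study_index=t)
                total += len(lesions)
                series.append((t, lesions))
            tracks = build_tracks(series)
            present = sum(1 for tr in tracks for m in tr.measurements if m.present)
            assert present == total

    def test_relabeling_invariance(self):
        series_a = [
            (0, lesions_from_cubes([(2, 2, 2, 5), (25, 25, 4, 3)])),
            (1, lesions_from_cubes([(2, 2, 2, 3), (25, 25, 4, 5)])),
        ]
        tracks = build_tracks(series_a)
        # the geometry is symmetric under which id each lesion got; verify by
        # checking both tracks stay at fixed locations (footprint continuity)
        assert len(tracks) == 2
        for tr in tracks:
            assert all(m.present for m in tr.measurements)


def test_phantom_matching_parameter_recovery():
    """Matched pairs equal ground-truth correspondence on 100 random phantoms."""
    for seed in range(100):
        cfg = PhantomConfig(shape=(48, 48, 20), n_studies=3, n_lesions=2,
                            diameter_range_mm=(4.0, 7.0),
                            trajectories=[Trajectory("flat"), Trajectory("grow", 10.0)],
                            seed=seed)
        volumes, truth = generate_phantom(cfg)
        per_study = []
        for vol in volumes:
            lesions = measure_lesions(extract_lesions(vol), vol.grid)
            # identify each extracted lesion with the nearest truth center
            ids = {}
            for l in lesions:
                dists = [np.linalg.norm(l.centroid_mm - tl.center_mm) for tl in truth.lesions]
                ids[l.lesion_id] = truth.lesions[int(np.argmin(dists))].lesion_id
            per_study.append((lesions, ids))
        for (prev, prev_ids), (curr, curr_ids) in zip(per_study, per_study[1:]):
            m = match_lesions(prev, curr)
            for a, b in m.pairs:
                assert prev_ids[a] == curr_ids[b]
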