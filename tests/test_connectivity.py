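import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perifc import connectivity as conn
from perifc import lesion_masks as lm
from perifc.volumes_io import BinaryMask, Volume4D, VoxelGrid

from .conftest import small_subject_volume
from .oracles import brute_sphere_offsets, pearson, triple_loop_difference_map


class TestSphereOffsets:
    def test_scanner_geometry_gives_face_neighbours(self):
        """At 5 mm radius on 3.75/3.75/4 mm voxels only the 6 face neighbours fit."""
        offsets = conn.sphere_offsets(5.0, (3.75, 3.75, 4.0))
        assert sorted(offsets) == brute_sphere_offsets(5.0, (3.75, 3.75, 4.0))
        assert len(offsets) == 7
        assert (0, 0, 0) in offsets

    def test_sub_voxel_radius(self):
        assert conn.sphere_offsets(0.5, (1.0, 1.0, 1.0)) == [(0, 0, 0)]

    def test_isotropic_unit_ball(self):
        offsets = conn.sphere_offsets(1.0, (1.0, 1.0, 1.0))
        assert sorted(offsets) == brute_sphere_offsets(1.0, (1.0, 1.0, 1.0))
        assert len(offsets) == 7


class TestSeedSeries:
    def test_constant_sphere(self, scanner_grid):
        data = np.full(scanner_grid.dims + (5,), 3.0)
        vol = Volume4D(scanner_grid, data)
        allowed = BinaryMask(scanner_grid, np.ones(scanner_grid.dims, dtype=bool))
        offsets = conn.sphere_offsets(5.0, scanner_grid.voxel_mm)
        ts = conn.seed_series(vol, (4, 4, 3), offsets, allowed)
        np.testing.assert_allclose(ts, 3.0)

    def test_cavity_voxels_excluded_from_mean(self, scanner_grid, rng):
        data = rng.normal(size=scanner_grid.dims + (10,))
        vol = Volume4D(scanner_grid, data)
        allowed_arr = np.ones(scanner_grid.dims, dtype=bool)
        allowed_arr[5, 4, 3] = False  # cavity voxel adjacent to the seed
        allowed = BinaryMask(scanner_grid, allowed_arr)
        offsets = conn.sphere_offsets(5.0, scanner_grid.voxel_mm)
        ts = conn.seed_series(vol, (4, 4, 3), offsets, allowed)
        manual = [
            data[i, j, k]
            for (di, dj, dk) in offsets
            for (i, j, k) in [(4 + di, 4 + dj, 3 + dk)]
            if allowed_arr[i, j, k]
        ]
        np.testing.assert_allclose(ts, np.mean(manual, axis=0))

    def test_matches_brute_force_mean(self, rng):
        grid = VoxelGrid((6, 6, 6), (1.0, 1.0, 1.0), tr_s=2.0)
        data = rng.normal(size=(6, 6, 6, 8))
        vol = Volume4D(grid, data)
        allowed = BinaryMask(grid, np.ones((6, 6, 6), dtype=bool))
        offsets = conn.sphere_offsets(1.5, grid.voxel_mm)
        ts = conn.seed_series(vol, (3, 3, 3), offsets, allowed)
        manual = np.mean(
            [data[3 + o[0], 3 + o[1], 3 + o[2]] for o in offsets], axis=0
        )
        np.testing.assert_allclose(ts, manual, rtol=1e-12)

    def test_isolated_seed_fails(self, scanner_grid, rng):
        vol = Volume4D(scanner_grid, rng.normal(size=scanner_grid.dims + (5,)))
        allowed = BinaryMask(scanner_grid, np.zeros(scanner_grid.dims, dtype=bool))
        offsets = conn.sphere_offsets(5.0, scanner_grid.voxel_mm)
        with pytest.raises(conn.EmptySphereError):
            conn.seed_series(vol, (4, 4, 3), offsets, allowed)


class TestFisherZ:
    def test_zero(self):
        assert conn.fisher_z(0.0) == 0.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
    def test_odd_function(self, r):
        assert conn.fisher_z(-r) == pytest.approx(-conn.fisher_z(r), abs=1e-12)

    def test_half(self):
        # high-precision atanh(0.5)
        assert conn.fisher_z(0.5) == pytest.approx(0.5493061443340548, abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            conn.fisher_z(1.5)

    def test_perfect_correlation_clipped(self):
        assert conn.fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))


class TestSeedWholebrainZ:
    def test_identical_targets_hit_clip_ceiling(self, rng):
        grid = VoxelGrid((3, 3, 3), (1, 1, 1), tr_s=2.0)
        ts = rng.normal(size=20)
        data = np.broadcast_to(ts, (3, 3, 3, 20)).copy()
        vol = Volume4D(grid, data)
        target = BinaryMask(grid, np.ones((3, 3, 3), dtype=bool))
        z = conn.seed_wholebrain_z(vol, ts, target)
        assert z.value == pytest.approx(np.arctanh(1 - 1e-7))

    def test_independent_noise_near_zero(self, rng):
        n_frames, dims = 200, (6, 6, 6)
        grid = VoxelGrid(dims, (1, 1, 1), tr_s=2.0)
        vol = Volume4D(grid, rng.normal(size=dims + (n_frames,)))
        target = BinaryMask(grid, np.ones(dims, dtype=bool))
        seed_ts = rng.normal(size=n_frames)
        z = conn.seed_wholebrain_z(vol, seed_ts, target)
        # Fisher-z null SD is 1/sqrt(n-3); the mean over V weakly dependent
        # targets shrinks it by ~sqrt(V)
        bound = 3.0 * (1 / np.sqrt(n_frames - 3)) / np.sqrt(target.n_voxels)
        assert abs(z.value) < bound

    def test_matches_triple_loop_oracle(self, rng):
        dims = (5, 5, 5)
        grid = VoxelGrid(dims, (1, 1, 1), tr_s=2.0)
        data = rng.normal(size=dims + (30,))
        vol = Volume4D(grid, data)
        target = BinaryMask(grid, rng.random(dims) > 0.3)
        seed_ts = rng.normal(size=30)
        z = conn.seed_wholebrain_z(vol, seed_ts, target)
        zs = []
        for idx in np.argwhere(target.data):
            r = pearson(seed_ts, data[tuple(idx)])
            zs.append(np.arctanh(np.clip(r, -(1 - 1e-7), 1 - 1e-7)))
        assert z.value == pytest.approx(np.mean(zs), abs=1e-12)

    def test_constant_seed_rejected(self, rng):
        grid = VoxelGrid((3, 3, 3), (1, 1, 1), tr_s=2.0)
        vol = Volume4D(grid, rng.normal(size=(3, 3, 3, 10)))
        target = BinaryMask(grid, np.ones((3, 3, 3), dtype=bool))
        with pytest.raises(conn.ConstantSeedError):
            conn.seed_wholebrain_z(vol, np.ones(10), target)

    def test_zero_variance_targets_counted_as_zero(self, rng):
        grid = VoxelGrid((3, 3, 3), (1, 1, 1), tr_s=2.0)
        data = rng.normal(size=(3, 3, 3, 15))
        data[0, 0, 0] = 5.0  # flat voxel
        vol = Volume4D(grid, data)
        target = BinaryMask(grid, np.ones((3, 3, 3), dtype=bool))
        z = conn.seed_wholebrain_z(vol, rng.normal(size=15), target)
        assert z.n_zero_variance == 1


class TestDifferenceMap:
    def _setup(self, rng, dims=(8, 8, 8), n_frames=40):
        vol, brain, resection = small_subject_volume(rng, dims=dims, n_frames=n_frames)
        mset = lm.build_mask_set(resection, brain, iterations=2)
        offsets = conn.sphere_offsets(5.0, vol.grid.voxel_mm)
        pairs = conn.make_seed_pairs(
            mset.perilesional, mset.brain, allowed=mset.cavity_excluded_brain
        )
        return vol, mset, offsets, pairs

    def test_matches_triple_loop_oracle(self, rng):
        vol, mset, offsets, pairs = self._setup(rng)
        dm = conn.difference_map(vol, pairs, offsets, mset.cavity_excluded_brain)
        peri_voxels = [p.peri_index for p in pairs if p.paired]
        entries, metric = triple_loop_difference_map(
            vol.series,
            peri_voxels,
            vol.grid.dims,
            vol.grid.left_right_axis,
            offsets,
            mset.cavity_excluded_brain.data,
        )
        assert dm.subject_metric == pytest.approx(metric, abs=1e-10)
        for k, v in entries.items():
            assert dm.entries[k] == pytest.approx(v, abs=1e-10)

    def test_scale_invariance(self, rng):
        """Pearson r (hence every z) is invariant to positive rescaling."""
        vol, mset, offsets, pairs = self._setup(rng)
        dm1 = conn.difference_map(vol, pairs, offsets, mset.cavity_excluded_brain)
        vol2 = Volume4D(vol.grid, vol.series * 37.5)
        dm2 = conn.difference_map(vol2, pairs, offsets, mset.cavity_excluded_brain)
        assert dm2.subject_metric == pytest.approx(dm1.subject_metric, abs=1e-12)

    def test_difference_order_identity(self, rng):
        """difference-of-averages equals average-of-voxelwise-differences."""
        vol, mset, offsets, pairs = self._setup(rng)
        dm = conn.difference_map(vol, pairs, offsets, mset.cavity_excluded_brain)
        corr = conn._TargetCorrelator(vol, mset.cavity_excluded_brain)
        pair = next(p for p in pairs if p.paired)
        ts_p = conn.seed_series(vol, pair.peri_index, offsets, mset.cavity_excluded_brain)
        ts_c = conn.seed_series(vol, pair.contra_index, offsets, mset.cavity_excluded_brain)
        sc_p = (ts_p - ts_p.mean()) / np.linalg.norm(ts_p - ts_p.mean())
        sc_c = (ts_c - ts_c.mean()) / np.linalg.norm(ts_c - ts_c.mean())
        z_p = np.arctanh(np.clip(corr.Xn @ sc_p, -(1 - 1e-7), 1 - 1e-7))
        z_c = np.arctanh(np.clip(corr.Xn @ sc_c, -(1 - 1e-7), 1 - 1e-7))
        voxelwise_then_mean = float(np.mean(z_p - z_c))
        assert dm.entries[pair.peri_index] == pytest.approx(voxelwise_then_mean, abs=1e-10)

    def test_zero_paired_seeds_fails(self, rng):
        vol, mset, offsets, pairs = self._setup(rng)
        unpaired = [
            conn.SeedPair(p.peri_index, p.contra_index, False) for p in pairs
        ]
        with pytest.raises(conn.NoPairedSeedsError):
            conn.difference_map(vol, unpaired, offsets, mset.cavity_excluded_brain)

    def test_unpaired_seeds_counted(self, rng):
        vol, mset, offsets, pairs = self._setup(rng)
        pairs2 = list(pairs)
        pairs2[0] = conn.SeedPair(pairs2[0].peri_index, pairs2[0].contra_index, False)
        dm = conn.difference_map(vol, pairs2, offsets, mset.cavity_excluded_brain)
        assert dm.n_unpaired == 1
        assert dm.n_pairs == len(pairs2) - 1


class TestHeatmap:
    def _dm(self, entries):
        grid = VoxelGrid((4, 4, 4), (1, 1, 1))
        return conn.DifferenceMap(
            grid=grid,
            entries=entries,
            z_peri={k: 0.0 for k in entries},
            z_contra={k: 0.0 for k in entries},
            subject_metric=float(np.mean(list(entries.values()))) if entries else 0.0,
            n_pairs=len(entries),
            n_unpaired=0,
            n_zero_variance_targets=0,
        )

    def test_empty_entries_all_zero(self):
        vol = conn.heatmap_volume(self._dm({}))
        assert not vol.values.any()

    def test_single_entry(self):
        vol = conn.heatmap_volume(self._dm({(1, 2, 3): 0.3}))
        assert vol.values[1, 2, 3] == pytest.approx(0.3)
        assert np.count_nonzero(vol.values) == 1

    def test_sum_conservation(self, rng):
        entries = {(int(i), int(i), int(i)): float(v) for i, v in enumerate(rng.normal(size=4))}
        vol = conn.heatmap_volume(self._dm(entries))
        assert vol.values.sum() == pytest.approx(sum(entries.values()))
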