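"""Islet architecture: loading, overlap counting, packing, rasterization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import isletvasc as iv
from isletvasc.core import ALPHA, BETA, DELTA
from isletvasc.geometry import count_overlaps


def _write_table(path, rows):
    pd.DataFrame(rows, columns=["x", "y", "z", "type", "radius"]).to_csv(
        path, index=False)
    return path


def _brute_force_overlaps(arch):
    """Independent O(n^2) recount straight from the definition."""
    n = arch.n_cells
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(arch.centers[i], arch.centers[j])
            if d < arch.radii[i] + arch.radii[j] - 1e-12:
                count += 1
    return count


class TestLoadCells:
    def test_counts_per_type_reported(self, tmp_path, rng):
        # 583 cells: 148 alpha, 316 beta, 119 delta
        rows = []
        for n, t in ((148, "alpha"), (316, "beta"), (119, "delta")):
            for _ in range(n):
                x, y, z = rng.uniform(0, 300, 3)
                rows.append((x, y, z, t, 5.0))
        arch = iv.load_cells(_write_table(tmp_path / "c.csv", rows))
        assert arch.n_cells == 583
        assert arch.counts() == {"alpha": 148, "beta": 316, "delta": 119}

    def test_env_is_extent_plus_buffer(self, tmp_path):
        arch = iv.load_cells(_write_table(tmp_path / "c.csv",
                                          [(0.0, 0.0, 0.0, "beta", 5.0)]))
        assert arch.env_dims == (70, 70, 70)  # diameter 10 + 2 x 30 buffer

    def test_published_env_rule(self, tmp_path):
        # two corner cells spanning the extents of published islet 1
        r = 5.0
        ext = (227 - 60, 208 - 60, 164 - 60)
        rows = [(r, r, r, "beta", r),
                (ext[0] - r, ext[1] - r, ext[2] - r, "alpha", r)]
        arch = iv.load_cells(_write_table(tmp_path / "c.csv", rows))
        assert arch.env_dims == (227, 208, 164)

    def test_unknown_type_token_names_row(self, tmp_path):
        p = _write_table(tmp_path / "c.csv",
                         [(0, 0, 0, "beta", 5), (1, 9, 9, "pp", 5)])
        with pytest.raises(ValueError, match="'pp' in row 1"):
            iv.load_cells(p)

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises((ValueError, pd.errors.EmptyDataError)):
            iv.load_cells(_write_table(tmp_path / "c.csv", []))

    def test_missing_radii_drawn_from_distribution(self, tmp_path):
        df = pd.DataFrame({"x": [0.0, 20.0], "y": [0.0, 0.0], "z": [0.0, 0.0],
                           "type": ["beta", "alpha"]})
        df.to_csv(tmp_path / "c.csv", index=False)
        arch = iv.load_cells(tmp_path / "c.csv", seed=3)
        dist = iv.RadiiDistribution()
        assert np.all((arch.radii >= dist.lower) & (arch.radii <= dist.upper))


class TestCountOverlaps:
    def test_single_cell(self):
        arch = iv.IsletArchitecture([[0, 0, 0]], [5.0], [BETA])
        assert count_overlaps(arch) == 0

    @pytest.mark.parametrize("distance,expected", [(8.0, 1), (10.0, 0)])
    def test_tangency_is_not_an_overlap(self, distance, expected):
        arch = iv.IsletArchitecture([[0, 0, 0], [distance, 0, 0]],
                                    [5.0, 5.0], [BETA, BETA])
        assert count_overlaps(arch) == expected

    def test_matches_brute_force_recount(self, rng):
        centers = rng.uniform(0, 60, size=(50, 3))
        radii = rng.uniform(3.5, 8.0, size=50)
        arch = iv.IsletArchitecture(centers, radii, [BETA] * 50)
        assert count_overlaps(arch) == _brute_force_overlaps(arch)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_invariant_under_reordering_and_translation(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 20))
        centers = r.uniform(0, 40, size=(n, 3))
        radii = r.uniform(3.5, 8.0, size=n)
        base = iv.IsletArchitecture(centers, radii, [BETA] * n)
        perm = r.permutation(n)
        shuffled = iv.IsletArchitecture(centers[perm], radii[perm], [BETA] * n)
        shifted = iv.IsletArchitecture(centers + r.uniform(-30, 30, 3),
                                       radii, [BETA] * n)
        assert count_overlaps(base) == count_overlaps(shuffled)
        assert count_overlaps(base) == count_overlaps(shifted)


class TestOptimizePacking:
    def test_overlap_free_input_unchanged(self):
        arch = iv.IsletArchitecture([[0, 0, 0], [20, 0, 0]], [5.0, 5.0],
                                    [BETA, ALPHA])
        out = iv.optimize_packing(arch, max_iter=100, seed=0)
        np.testing.assert_allclose(out.centers, arch.centers)
        np.testing.assert_allclose(out.radii, arch.radii)

    def test_two_overlapping_spheres_resolve(self):
        arch = iv.IsletArchitecture([[50, 50, 50], [53, 50, 50]], [5.0, 5.0],
                                    [BETA, BETA], env_dims=(100, 100, 100))
        out = iv.optimize_packing(arch, max_iter=10_000, seed=1)
        assert count_overlaps(out) == 0
        assert out.meta["packing"]["converged"]

    def test_deterministic_under_seed(self, rng):
        centers = rng.uniform(0, 40, size=(20, 3))
        arch = iv.IsletArchitecture(centers, [5.0] * 20, [BETA] * 20)
        a = iv.optimize_packing(arch, max_iter=2000, seed=7)
        b = iv.optimize_packing(arch, max_iter=2000, seed=7)
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_array_equal(a.radii, b.radii)

    def test_best_trajectory_non_increasing(self, rng):
        centers = rng.uniform(0, 35, size=(25, 3))
        arch = iv.IsletArchitecture(centers, [5.5] * 25, [BETA] * 25)
        out = iv.optimize_packing(arch, max_iter=3000, seed=2)
        traj = out.meta["packing"]["best_trajectory"]
        assert np.all(np.diff(traj) <= 0)
        assert count_overlaps(out) == traj[-1]


class TestSynthesizeIslet:
    def test_counts_match_composition(self):
        arch = iv.synthesize_islet(583, "human", target_diameter=112, seed=5)
        assert count_overlaps(arch) == 0
        counts = arch.counts()
        from scipy.stats import chisquare
        obs = [counts["alpha"], counts["beta"], counts["delta"]]
        exp = [583 * f for f in (0.29, 0.53, 0.18)]
        assert chisquare(obs, exp).pvalue > 1e-3

    def test_pure_beta_mouse(self):
        arch = iv.synthesize_islet(10, "mouse", {"beta": 1.0},
                                   target_diameter=40, seed=1)
        assert arch.counts() == {"alpha": 0, "beta": 10, "delta": 0}

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError, match="infeasible density"):
            iv.synthesize_islet(200, target_diameter=40, seed=0)

    def test_large_published_size_is_feasible(self, rng):
        # 3,516 cells in a 360 µm ball stay below the 0.64 density cap
        radii = iv.RadiiDistribution().sample(3516, rng)
        total = float(np.sum(4 / 3 * math.pi * radii ** 3))
        assert total <= 0.64 * math.pi / 6 * 360 ** 3

    def test_bit_reproducible_under_seed(self):
        a = iv.synthesize_islet(30, target_diameter=44, seed=9)
        b = iv.synthesize_islet(30, target_diameter=44, seed=9)
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_array_equal(a.radii, b.radii)
        np.testing.assert_array_equal(a.types, b.types)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            iv.synthesize_islet(10, composition={"beta": 0.5}, seed=0)


class TestRasterize:
    def test_sphere_voxel_count_matches_enumeration_oracle(self):
        arch = iv.IsletArchitecture([[0, 0, 0]], [5.0], [BETA])
        grid = iv.rasterize(arch)
        count = int((grid.labels == 1).sum())
        # independent enumeration of voxel centers within the sphere
        c = arch.centers[0]
        expected = 0
        for i in range(60):
            for j in range(60):
                for k in range(60):
                    d2 = ((i + 0.5 - c[0]) ** 2 + (j + 0.5 - c[1]) ** 2
                          + (k + 0.5 - c[2]) ** 2)
                    expected += d2 <= 25.0
        assert count == expected
        # voxelization bias vs the continuum volume: about half a voxel of
        # surface dilation, ~5 % at r = 5
        vol = 4 / 3 * math.pi * 125
        assert abs(count - vol) / vol < 0.06

    def test_empty_architecture_all_medium(self):
        arch = iv.IsletArchitecture(np.zeros((0, 3)), [], [])
        grid = iv.rasterize(arch)
        assert grid.labels.shape == (60, 60, 60)
        assert not grid.labels.any()

    def test_labels_partition_grid(self, small_islet, small_grid):
        counts = np.bincount(small_grid.labels.ravel(),
                             minlength=small_islet.n_cells + 1)
        assert counts.sum() == small_grid.labels.size
        for cid in small_islet.cell_ids:
            r = small_islet.radii[cid - 1]
            assert 0 < counts[cid] <= (2 * r + 1) ** 3

    def test_overlapping_architecture_rejected(self):
        arch = iv.IsletArchitecture([[0, 0, 0], [3, 0, 0]], [5.0, 5.0],
                                    [BETA, ALPHA])
        with pytest.raises(ValueError, match="overlap-free"):
            iv.rasterize(arch)


def test_mouse_architecture_rejects_delta_cells():
    with pytest.raises(ValueError, match="delta"):
        iv.IsletArchitecture([[0, 0, 0]], [5.0], [DELTA], species="mouse")


def test_cell_table_roundtrip(tmp_path, small_islet):
    small_islet.save_cells(tmp_path / "cells.csv")
    back = iv.load_cells(tmp_path / "cells.csv", species="human")
    assert back.n_cells == small_islet.n_cells
    assert back.counts() == small_islet.counts()
    np.testing.assert_allclose(np.sort(back.radii), np.sort(small_islet.radii))
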