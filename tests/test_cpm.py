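"""Cellular Potts capillary growth: energies, Metropolis dynamics, invariants."""

import math

import numpy as np
import pytest

import isletvasc as iv
from isletvasc.core import BETA, CAPILLARY, LabeledGrid
from isletvasc.cpm import (CPMConfig, _interface_offsets, attempt_copy,
                           delta_energy, metropolis_accept, seed_state,
                           target_volume, total_energy)
from isletvasc.seeding import CapillaryPath

from conftest import make_grid


def _straight_path(path_id, axis, n, y, z):
    if axis == "x":
        vox = np.array([(i, y, z) for i in range(n)], dtype=np.int32)
    return CapillaryPath(path_id, axis, vox, tuple(vox[0]), tuple(vox[-1]))


def _brute_force_energy(state, cfg):
    """Independent double-loop Hamiltonian recomputation."""
    labels = state.grid.labels
    types = state.grid.type_of
    offs = _interface_offsets(cfg.neighbor_order)
    nx, ny, nz = labels.shape
    H = 0.0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                for dx, dy, dz in offs:
                    u = (x + dx, y + dy, z + dz)
                    if not (0 <= u[0] < nx and 0 <= u[1] < ny and 0 <= u[2] < nz):
                        continue
                    if labels[x, y, z] != labels[u]:
                        H += 0.5 * cfg.J[types[labels[x, y, z]], types[labels[u]]]
    for e in range(state.volumes.size):
        if state.lam[e] > 0 and not state.frozen[e]:
            H += state.lam[e] * (state.volumes[e] - state.target_volumes[e]) ** 2
    return H


def _random_state(seed, shape=(7, 7, 7)):
    r = np.random.default_rng(seed)
    labels = r.integers(0, 4, size=shape).astype(np.int32)
    type_of = np.array([0, BETA, CAPILLARY, CAPILLARY], dtype=np.int8)
    grid = LabeledGrid(labels, type_of)
    volumes = np.bincount(labels.ravel(), minlength=4).astype(np.int64)
    tv = np.array([0.0, 0.0, 40.0, 80.0])
    lam = np.array([0.0, 0.0, 1e3, 1e3])
    frozen = np.array([False, True, False, False])
    return iv.CPMState(grid, volumes, tv, lam, frozen)


class TestTargetVolume:
    def test_published_formula(self):
        assert target_volume(3.5, 100.0) == pytest.approx(
            2 * math.pi * 3.5**2 * 100, rel=1e-12)
        assert target_volume(3.5, 100.0) == pytest.approx(7696.9, abs=0.05)

    def test_zero_length(self):
        assert target_volume(3.5, 0.0) == 0.0

    def test_linearity_in_length(self):
        assert target_volume(3.5, 200.0) == pytest.approx(
            2 * target_volume(3.5, 100.0))

    def test_cylinder_mode_is_half(self):
        cfg = CPMConfig(doubled_target_volume=False)
        assert cfg.capillary_target_volume(100.0) == pytest.approx(
            0.5 * target_volume(3.5, 100.0))


class TestConfigValidation:
    def test_asymmetric_table_rejected(self):
        J = np.zeros((5, 5))
        J[0, 1] = 5.0
        with pytest.raises(ValueError, match="symmetric"):
            CPMConfig(J=J)

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            CPMConfig(T=0.0)


class TestTotalEnergy:
    def test_all_medium_is_zero(self):
        state = iv.CPMState(make_grid((4, 4, 4)),
                            np.array([64], dtype=np.int64),
                            np.zeros(1), np.zeros(1), np.zeros(1, dtype=bool))
        assert total_energy(state, CPMConfig()) == 0.0

    def test_single_capillary_voxel_hand_count(self):
        # 6 capillary/medium interfaces + volume penalty (v=1, V=10, lam=1e3)
        grid = make_grid((3, 3, 3), [(1, CAPILLARY, np.s_[1, 1, 1])])
        state = iv.CPMState(grid, np.array([26, 1], dtype=np.int64),
                            np.array([0.0, 10.0]), np.array([0.0, 1e3]),
                            np.array([False, False]))
        cfg = CPMConfig(neighbor_order=1)
        assert total_energy(state, cfg) == pytest.approx(
            6 * 70 + 1e3 * 81, rel=1e-12)

    @pytest.mark.parametrize("order", [1, 2])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, order, seed):
        state = _random_state(seed)
        cfg = CPMConfig(neighbor_order=order)
        assert total_energy(state, cfg) == pytest.approx(
            _brute_force_energy(state, cfg), rel=1e-12)


class TestDeltaEnergy:
    @pytest.mark.parametrize("seed", range(4))
    def test_consistent_with_total_energy_difference(self, seed):
        state = _random_state(seed)
        cfg = CPMConfig()
        r = np.random.default_rng(seed + 100)
        for _ in range(20):
            site = tuple(r.integers(0, 7, 3))
            d = r.integers(0, 3)
            nb = list(site)
            nb[d] += 1 if nb[d] < 6 else -1
            nb = tuple(nb)
            ss, sn = state.grid.labels[site], state.grid.labels[nb]
            if ss == sn:
                continue
            dH = delta_energy(state, site, nb, cfg)
            before = total_energy(state, cfg)
            state.grid.labels[site] = sn
            state.volumes[ss] -= 1
            state.volumes[sn] += 1
            after = total_energy(state, cfg)
            assert dH == pytest.approx(after - before, rel=1e-9, abs=1e-6)


class TestAttemptCopy:
    def test_frozen_cell_target_rejected(self):
        grid = make_grid((5, 5, 5), [(1, BETA, np.s_[2, 2, 2]),
                                     (2, CAPILLARY, np.s_[0, 0, 0])])
        state = seed_state_like(grid)
        before = grid.labels.copy()
        accepted = attempt_copy(state, (2, 2, 2), (2, 2, 3), CPMConfig(),
                                np.random.default_rng(0))
        assert not accepted
        np.testing.assert_array_equal(state.grid.labels, before)

    def test_zero_delta_always_accepted(self):
        # two capillary halves, zero contact energies, no volume constraint:
        # every cross-boundary copy has dH = 0 and must be accepted
        grid = make_grid((4, 4, 4), [(1, CAPILLARY, np.s_[:2, :, :]),
                                     (2, CAPILLARY, np.s_[2:, :, :])])
        state = iv.CPMState(grid, np.array([0, 32, 32], dtype=np.int64),
                            np.zeros(3), np.zeros(3),
                            np.zeros(3, dtype=bool))
        cfg = CPMConfig(J=np.zeros((5, 5)), lambda_vol=0.0)
        assert delta_energy(state, (1, 0, 0), (2, 0, 0), cfg) == 0.0
        assert attempt_copy(state, (1, 0, 0), (2, 0, 0), cfg,
                            np.random.default_rng(0))
        assert state.grid.labels[1, 0, 0] == 2
        assert state.volumes[1] == 31 and state.volumes[2] == 33

    def test_metropolis_rate_at_dh_equal_t(self, rng):
        trials = 100_000
        hits = sum(metropolis_accept(10.0, 10.0, rng) for _ in range(trials))
        p = math.exp(-1)
        se = math.sqrt(p * (1 - p) / trials)
        assert abs(hits / trials - p) < 3 * se


def seed_state_like(grid):
    n = grid.type_of.size
    volumes = np.bincount(grid.labels.ravel(), minlength=n).astype(np.int64)
    lam = np.where(grid.type_of == CAPILLARY, 1e3, 0.0)
    tv = np.where(grid.type_of == CAPILLARY, 50.0, 0.0)
    frozen = np.isin(grid.type_of, (1, 2, 3))
    return iv.CPMState(grid, volumes, tv, lam, frozen)


class TestEvolve:
    def test_zero_mcs_returns_seeded_grid(self):
        grid = make_grid((20, 10, 10))
        path = _straight_path(1, "x", 20, 5, 5)
        cfg = CPMConfig(n_mcs=0)
        out, report = iv.evolve_capillaries(grid, [path], cfg, seed=1)
        expected = seed_state(grid, [path], cfg).grid
        np.testing.assert_array_equal(out.labels, expected.labels)

    def test_single_path_grows_to_target_volume(self):
        grid = make_grid((60, 60, 60))
        path = _straight_path(1, "x", 60, 30, 30)
        cfg = CPMConfig(n_mcs=200)
        out, report = iv.evolve_capillaries(grid, [path], cfg, seed=2)
        v, tv = report["capillary_volumes"][1], report["capillary_target_volumes"][1]
        assert abs(v - tv) / tv < 0.10
        # cross-section perpendicular to the tube axis: effective diameter
        disc = out.labels[30, :, :] == 1
        d_eff = 2 * math.sqrt(disc.sum() / math.pi)
        assert 5.0 <= d_eff <= 10.0

    def test_parallel_capillaries_do_not_merge(self):
        grid = make_grid((40, 40, 40))
        p1 = _straight_path(1, "x", 40, 18, 20)
        p2 = _straight_path(2, "x", 40, 22, 20)
        out, _ = iv.evolve_capillaries(grid, [p1, p2], CPMConfig(n_mcs=150),
                                       seed=3)
        # count 6-adjacent voxel pairs carrying different capillary IDs
        contacts = 0
        lab = out.labels
        for ax in range(3):
            a = np.moveaxis(lab, ax, 0)
            pair = (a[:-1] != a[1:]) & (a[:-1] > 0) & (a[1:] > 0)
            contacts += int(pair.sum())
        assert contacts == 0

    def test_frozen_cells_bit_identical(self, small_grid):
        pool = iv.generate_initial_capillaries(small_grid, n_per_axis=2, seed=5)
        cell_mask = small_grid.labels > 0
        before = small_grid.labels[cell_mask].copy()
        out, _ = iv.evolve_capillaries(small_grid, pool, CPMConfig(n_mcs=30),
                                       seed=6)
        np.testing.assert_array_equal(out.labels[cell_mask], before)

    def test_volume_bookkeeping_matches_recount(self, small_vascularized):
        vgrid, paths, report = small_vascularized
        recount = np.bincount(vgrid.labels.ravel(),
                              minlength=vgrid.type_of.size)
        for p in paths:
            assert report["capillary_volumes"][p.path_id] == recount[p.path_id]

    def test_incremental_energy_matches_recomputation(self, small_vascularized):
        _, _, report = small_vascularized
        assert report["bookkeeping_rel_drift"] <= 1e-6
        np.testing.assert_allclose(report["H_incremental"],
                                   report["H_recomputed"], rtol=1e-6)

    def test_energy_decreases_during_growth(self, small_vascularized):
        _, _, report = small_vascularized
        H = report["H_recomputed"]
        assert H[-1] < H[0]
        # smoothed trajectory non-increasing within 5% tolerance
        k = 3
        smooth = np.convolve(H, np.ones(k) / k, mode="valid")
        assert np.all(np.diff(smooth) <= 0.05 * np.abs(smooth[:-1]) + 1e-9)

    def test_infinite_temperature_accepts_everything(self):
        grid = make_grid((20, 20, 20))
        path = _straight_path(1, "x", 20, 10, 10)
        cfg = CPMConfig(T=1e12, lambda_vol=0.0, n_mcs=20)
        _, report = iv.evolve_capillaries(grid, [path], cfg, seed=9)
        assert report["evaluated"] > 0
        assert report["accepted"] / report["evaluated"] > 0.999

    def test_same_seed_identical_lattice(self):
        grid = make_grid((25, 25, 25))
        path = _straight_path(1, "x", 25, 12, 12)
        a, _ = iv.evolve_capillaries(grid, [path], CPMConfig(n_mcs=30), seed=4)
        b, _ = iv.evolve_capillaries(grid, [path], CPMConfig(n_mcs=30), seed=4)
        np.testing.assert_array_equal(a.labels, b.labels)
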