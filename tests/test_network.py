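"""Coupled-network simulator: coupling presets, initialization, integration."""

import numpy as np
import pytest

from splaycpg.network import (HOMOGENEOUS_G, SimulationConfig, build_coupling,
                              init_random_phases, simulate)
from splaycpg.stats import pair_sync_index, splayness


class TestCoupling:
    def test_homogeneous_values(self):
        G = build_coupling("homogeneous")
        off = G[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 0.0435)
        assert np.all(np.diag(G) == 0)

    def test_heterogeneous_structure_and_mean(self):
        G = build_coupling("heterogeneous")
        vals = G[np.triu_indices(5, k=1)]
        # grand mean of the ten pairwise conductances equals the homogeneous one
        assert np.mean(vals) == pytest.approx(HOMOGENEOUS_G, rel=1e-3)
        assert G[0, 1] == pytest.approx(0.08659)
        assert G[2, 3] == pytest.approx(0.08659)
        assert np.allclose(G[4, :4], 0.02719)
        assert G[0, 2] == pytest.approx(0.03827)
        # MN5 strength is half the mean of the non-MN5 connections
        non5 = [G[i, j] for i in range(4) for j in range(i + 1, 4)]
        assert G[4, 0] == pytest.approx(np.mean(non5) / 2, rel=1e-3)

    def test_explicit_zero_matrix_valid(self):
        G = build_coupling(matrix=np.zeros((5, 5)))
        assert np.all(G == 0)

    @pytest.mark.parametrize("bad", [
        np.ones((5, 4)),
        np.arange(25.0).reshape(5, 5),          # asymmetric
        -np.ones((5, 5)),                        # negative
    ])
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            build_coupling(matrix=bad)

    def test_gap_current_conservation(self):
        # sum over all ordered pairs of g_ij (v_j - v_i) vanishes for any
        # symmetric coupling matrix and any voltage vector
        rng = np.random.default_rng(0)
        for preset in ("homogeneous", "heterogeneous", "strong"):
            G = build_coupling(preset)
            v = rng.normal(-50, 20, size=5)
            total = sum(G[i, j] * (v[j] - v[i])
                        for i in range(5) for j in range(5) if i != j)
            assert abs(total) < 1e-9


class TestInitialization:
    def test_seeded_determinism(self, snl_params, snl_current, snl_cycle):
        a = init_random_phases(snl_params, snl_current, seed=7, cycle=snl_cycle)
        b = init_random_phases(snl_params, snl_current, seed=7, cycle=snl_cycle)
        assert all(x == y for x, y in zip(a, b))

    def test_phase_uniformity(self, snl_params, snl_current, snl_cycle):
        # draw 10^4 initial states, map each back to its cycle phase by
        # nearest neighbour in state space, and test uniformity
        from scipy.spatial import cKDTree
        from scipy.stats import chisquare
        states = init_random_phases(snl_params, snl_current, seed=1,
                                    cycle=snl_cycle, n=10000)
        tree = cKDTree(snl_cycle.states / snl_cycle.states.std(axis=0))
        pts = np.array([[s.v, s.b, s.h] for s in states])
        _, idx = tree.query(pts / snl_cycle.states.std(axis=0))
        phases = snl_cycle.phases[idx]
        counts, _ = np.histogram(phases, bins=16, range=(0, 1))
        assert chisquare(counts).pvalue > 0.01

    def test_explicit_phases_supported(self, snl_params, snl_current, snl_cycle):
        states = init_random_phases(snl_params, snl_current, seed=0,
                                    cycle=snl_cycle,
                                    phases=[0.0, 0.2, 0.4, 0.6, 0.8])
        vs = [s.v for s in states]
        assert len(set(np.round(vs, 6))) == 5


class TestSimulate:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(sigma=0.5, integrator="rk4")

    def test_uncoupled_preserves_period_and_offsets(self, snl_params, snl_current, snl_cycle):
        init = init_random_phases(snl_params, snl_current, seed=0,
                                  cycle=snl_cycle, phases=[0.1, 0.35, 0.6, 0.8, 0.95])
        cfg = SimulationConfig(duration=3.0, dt=0.05, sigma=0.0,
                               integrator="rk4", I_in=snl_current)
        res = simulate(snl_params, build_coupling(matrix=np.zeros((5, 5))),
                       cfg, initial_states=init)
        T = snl_cycle.period / 1000.0
        for t in res.trains.times:
            isi = np.diff(t[1:])
            assert np.allclose(isi, T, rtol=2e-3)

    def test_deterministic_reproducibility(self, snl_params, snl_current, snl_cycle):
        init = init_random_phases(snl_params, snl_current, seed=3, cycle=snl_cycle)
        cfg = SimulationConfig(duration=2.0, dt=0.05, sigma=0.0,
                               integrator="rk4", I_in=snl_current)
        r1 = simulate(snl_params, build_coupling("homogeneous"), cfg, initial_states=init)
        r2 = simulate(snl_params, build_coupling("homogeneous"), cfg, initial_states=init)
        for a, b in zip(r1.trains.times, r2.trains.times):
            assert np.array_equal(a, b)

    def test_heun_matches_rk4_without_noise(self, snl_params, snl_current, snl_cycle):
        init = init_random_phases(snl_params, snl_current, seed=5, cycle=snl_cycle)
        G = build_coupling("homogeneous")
        out = {}
        for integ in ("heun", "rk4"):
            cfg = SimulationConfig(duration=5.0, dt=0.005, sigma=0.0,
                                   integrator=integ, I_in=snl_current)
            out[integ] = simulate(snl_params, G, cfg, initial_states=init).trains
        for a, b in zip(out["heun"].times, out["rk4"].times):
            assert len(a) == len(b)
            assert np.max(np.abs(a - b)) * 1000 < 0.5   # ms

    def test_dt_halving_convergence(self, snl_params, snl_current, snl_cycle):
        init = init_random_phases(snl_params, snl_current, seed=2, cycle=snl_cycle)
        G = build_coupling("homogeneous")
        trains = {}
        for dt in (0.1, 0.05):
            cfg = SimulationConfig(duration=1.0, dt=dt, sigma=0.0,
                                   integrator="rk4", I_in=snl_current)
            trains[dt] = simulate(snl_params, G, cfg, initial_states=init).trains
        for a, b in zip(trains[0.1].times, trains[0.05].times):
            assert len(a) == len(b)
            if len(a):
                assert np.max(np.abs(a - b)) * 1000 < 0.1   # ms

    def test_strong_coupling_synchronizes(self, snl_params, snl_current, snl_cycle):
        init = init_random_phases(snl_params, snl_current, seed=11, cycle=snl_cycle)
        cfg = SimulationConfig(duration=10.0, dt=0.02, sigma=0.0,
                               integrator="rk4", I_in=snl_current)
        res = simulate(snl_params, build_coupling("strong"), cfg, initial_states=init)
        tr = res.trains.trimmed(5.0)
        assert splayness(tr) < 0.05
        assert pair_sync_index(tr[3], tr[4]) > 0.99

    def test_weak_coupling_splays(self, snl_params, snl_current, snl_cycle):
        init = init_random_phases(snl_params, snl_current, seed=11, cycle=snl_cycle)
        cfg = SimulationConfig(duration=15.0, dt=0.02, sigma=0.949,
                               seed=11, I_in=snl_current)
        res = simulate(snl_params, build_coupling("homogeneous"), cfg,
                       initial_states=init)
        assert splayness(res.trains.trimmed(3.0)) > 0.5
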