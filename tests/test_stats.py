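"""Spike-train statistics: phases, splayness, pair sync, histograms,
sequences, CV and group comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splaycpg.stats import (compare_index_sets, dip_fraction,
                            instantaneous_splayness, interpolate_phases,
                            isi_cv, pair_sync_index, phase_histogram,
                            sequence_statistics, splayness)
from splaycpg.trains import SpikeTrains


def periodic(rate, dur, offset=0.0):
    T = 1.0 / rate
    return np.arange(0.0, dur, T) + offset * T


class TestPhaseInterpolation:
    def test_values_at_spike_midpoint_and_advance(self):
        tr = SpikeTrains([periodic(5, 10), periodic(5, 10)])
        ps = interpolate_phases(tr)
        # grid starts at the first common spike: phase 0 there
        assert ps.phases[0, 0] == pytest.approx(0.0, abs=1e-9)
        # mid-ISI grid point (T = 200 ms -> k = 100) has phase 0.5
        assert ps.phases[100, 0] == pytest.approx(0.5, abs=1e-6)
        # linear advance of step/T per grid point
        d = np.diff(ps.phases[:50, 0])
        assert np.allclose(d, 0.001 / 0.2)

    def test_too_few_spikes_named_neuron(self):
        tr = SpikeTrains([periodic(5, 10), np.array([1.0])])
        with pytest.raises(ValueError, match="neuron 1"):
            interpolate_phases(tr)

    def test_breaks_are_omitted(self):
        tr = SpikeTrains([periodic(5, 20), periodic(5, 20)],
                         breaks=[(5.0, 8.0)])
        ps = interpolate_phases(tr)
        assert not np.any((ps.t > 5.0) & (ps.t < 8.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_closure_identity(self, seed):
        # sorted cyclic gaps of any phase configuration sum to exactly 1
        rng = np.random.default_rng(seed)
        phases = rng.random((50, 5))
        srt = np.sort(phases, axis=1)
        psi = np.column_stack([np.diff(srt, axis=1),
                               1 - (srt[:, -1] - srt[:, 0])])
        assert np.allclose(psi.sum(axis=1), 1.0)
        gamma = instantaneous_splayness(phases)
        assert np.all((gamma >= -1e-12) & (gamma <= 1 + 1e-12))


class TestSplayness:
    def test_perfect_splay_is_one(self):
        tr = SpikeTrains([periodic(8, 30, k / 5) for k in range(5)])
        assert splayness(tr) == pytest.approx(1.0, abs=1e-9)

    def test_perfect_sync_is_zero(self):
        tr = SpikeTrains([periodic(8, 30) for _ in range(5)])
        assert splayness(tr) == pytest.approx(0.0, abs=1e-12)

    def test_partial_configuration_closed_form(self):
        # instantaneous phases (0, 0, 0, 0, 0.5): gamma = 0.375
        gamma = instantaneous_splayness(np.array([[0, 0, 0, 0, 0.5]]))
        assert gamma[0] == pytest.approx(0.375)
        assert 1 - np.sqrt(0.375) == pytest.approx(0.38763, abs=1e-4)

    def test_two_neuron_antiphase_is_one(self):
        tr = SpikeTrains([periodic(8, 30), periodic(8, 30, 0.5)])
        assert splayness(tr) == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(0.1, 5.0), st.floats(0.0, 10.0))
    @settings(max_examples=15, deadline=None)
    def test_invariance_translation_and_rescaling(self, scale, shift):
        tr = SpikeTrains([periodic(8, 30, k / 5) for k in range(5)])
        tr2 = SpikeTrains([t * scale + shift for t in tr.times])
        assert splayness(tr2) == pytest.approx(splayness(tr), abs=1e-6)


class TestPairSync:
    def test_identical_trains(self):
        t = periodic(8, 30)
        assert pair_sync_index(t, t) == pytest.approx(1.0)

    def test_antiphase_cancels(self):
        assert pair_sync_index(periodic(8, 30), periodic(8, 30, 0.5)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_quarter_offset_closed_form(self):
        r = pair_sync_index(periodic(8, 30), periodic(8, 30, 0.25))
        assert r == pytest.approx(np.cos(np.pi * 0.25), abs=1e-6)

    def test_relabeling_symmetry(self):
        a, b = periodic(8, 30), periodic(7.3, 30, 0.3)
        assert pair_sync_index(a, b) == pytest.approx(pair_sync_index(b, a))


class TestPhaseHistogram:
    def test_identical_trains_mass_at_zero(self):
        t = periodic(8, 60)
        centers, rel = phase_histogram(t, t)
        assert rel.sum() == pytest.approx(1.0)
        assert rel[0] == pytest.approx(1.0)

    def test_constant_offset_mass_at_half(self):
        centers, rel = phase_histogram(periodic(8, 60), periodic(8, 60, 0.5))
        assert rel[50] == pytest.approx(1.0)

    def test_uniform_other_is_flat(self):
        from scipy.stats import chisquare
        rng = np.random.default_rng(0)
        ref = periodic(8, 400)
        other = np.sort(rng.uniform(0, 400, size=20000))
        _, rel = phase_histogram(ref, other)
        counts = rel * 20000
        assert chisquare(counts).pvalue > 0.01

    def test_trimming_removes_edges(self):
        ref = periodic(8, 20)
        with pytest.raises(ValueError):
            phase_histogram(np.array([0.1, 0.2]), np.array([0.15]), trim=3.0)


class TestDipFraction:
    def test_flat_histogram_gives_one_fifth(self):
        centers = (np.arange(100) - 50 + 0.5) / 100
        rel = np.full(100, 0.01)
        assert dip_fraction(centers, rel) == pytest.approx(0.2)

    def test_synchronized_pair_gives_one(self):
        t = periodic(8, 60)
        centers, rel = phase_histogram(t, t, centered=True)
        assert dip_fraction(centers, rel) == pytest.approx(1.0)

    def test_dip_anticorrelates_with_splayness(self):
        # jitter sweep on synthetic splay trains: more jitter lowers
        # splayness and fills in the dip around phase 0
        from splaycpg.synth import SynthConfig, gen_trains
        s_vals, dips = [], []
        for jit in (0.0, 0.05, 0.1, 0.2):
            tr = gen_trains(SynthConfig(rate_hz=8, duration_s=60, mode="splay",
                                        jitter=jit, seed=4))
            s_vals.append(splayness(tr))
            centers, rel = phase_histogram(tr[3], tr[4], centered=True)
            dips.append(dip_fraction(centers, rel))
        assert np.corrcoef(s_vals, dips)[0, 1] < 0


class TestSequences:
    def test_deterministic_order(self):
        # neurons 1,4,2,3 fire in that order each cycle
        T = 0.125
        tr = SpikeTrains([periodic(8, 30, 0.0), periodic(8, 30, 0.4),
                          periodic(8, 30, 0.6), periodic(8, 30, 0.2)])
        st_ = sequence_statistics(tr)
        assert st_["probabilities"]["1423"] == pytest.approx(1.0)
        assert st_["n_irregular"] == 0

    def test_irregular_cycles_counted_separately(self):
        tr = SpikeTrains([periodic(8, 30), periodic(4, 30, 0.2),
                          periodic(8, 30, 0.5), periodic(8, 30, 0.7)])
        st_ = sequence_statistics(tr)
        assert st_["n_irregular"] > 0

    def test_too_few_cycles_rejected(self):
        tr = SpikeTrains([np.array([0.0, 0.125]), np.array([0.02, 0.15]),
                          np.array([0.05, 0.18]), np.array([0.08, 0.2])])
        with pytest.raises(ValueError):
            sequence_statistics(tr)


class TestISICV:
    def test_periodic_is_zero(self):
        assert isi_cv(periodic(8, 30)) == pytest.approx(0.0)

    def test_poisson_near_one(self):
        rng = np.random.default_rng(1)
        t = np.cumsum(rng.exponential(0.125, size=5000))
        assert isi_cv(t) == pytest.approx(1.0, abs=0.05)

    def test_jittered_periodic_cv(self):
        rng = np.random.default_rng(2)
        T = 0.125
        t = np.sort(periodic(8, 600) + rng.normal(0, 0.1 * T, size=len(periodic(8, 600))))
        # independent jitter on consecutive spikes: CV ~ 0.1 * sqrt(2)
        assert isi_cv(t) == pytest.approx(0.1 * np.sqrt(2), rel=0.1)

    def test_too_few_spikes(self):
        with pytest.raises(ValueError):
            isi_cv(np.array([0.0]))


class TestGroupComparison:
    def test_identical_groups(self):
        a = list(range(10))
        U, p = compare_index_sets(a, a)
        assert p > 0.9
        assert U == pytest.approx(50.0)

    def test_complete_separation(self):
        a = np.linspace(1, 2, 10)
        b = np.linspace(3, 4, 10)
        U, p = compare_index_sets(b, a)
        assert U == 100.0
        assert p < 0.001

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(8), rng.random(12)
        U1, _ = compare_index_sets(a, b)
        U2, _ = compare_index_sets(b, a)
        assert U1 + U2 == pytest.approx(8 * 12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_index_sets([1, 2], [3, 4, 5])
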