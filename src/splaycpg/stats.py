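"""Spike-train statistics: phase interpolation, splayness, pairwise
synchronization, phase histograms, firing-sequence counts and group tests.

Phases are interpolated linearly between consecutive spikes of each neuron
on a common 1 ms grid spanning the interval from the first spike of the
last neuron to start spiking to the last spike of the first neuron to stop
(recording breaks excluded).  On that grid:

* the splayness index ``s`` compares the sorted cyclic phase gaps to the
  perfect splay (all gaps 1/N -> s = 1) and perfect synchrony (one gap of
  1 -> s = 0);
* the pairwise synchronization index ``r`` is the time-averaged modulus of
  the two-neuron Kuramoto order parameter, 1 for identical phases and 0
  for anti-phase firing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .trains import SpikeTrains

GRID_STEP_S = 1e-3

#: the six cyclic orders of MN2-4 within an MN1 cycle
SEQUENCE_CLASSES = ("1234", "1243", "1324", "1342", "1423", "1432")


@dataclass
class PhaseSeries:
    """Per-neuron phases in [0, 1) sampled on a common grid (s)."""

    t: np.ndarray          # (K,) grid times in s
    phases: np.ndarray     # (K, N)

    @property
    def n_neurons(self) -> int:
        return self.phases.shape[1]


def interpolate_phases(trains: SpikeTrains, step: float = GRID_STEP_S) -> PhaseSeries:
    """Linear phase interpolation on a common grid.

    phi_{k,i} = (tau_k - t_{n,i}) / (t_{n+1,i} - t_{n,i}) with
    t_{n,i} <= tau_k < t_{n+1,i}.  Grid points inside recording breaks are
    omitted.
    """
    for i, t in enumerate(trains.times):
        if len(t) < 2:
            raise ValueError(f"neuron {i} has fewer than 2 spikes; cannot interpolate phases")
    t_start = max(t[0] for t in trains.times)
    t_end = min(t[-1] for t in trains.times)
    if t_end <= t_start:
        raise ValueError("spike trains do not overlap")
    k = np.arange(int(np.floor((t_end - t_start) / step)) + 1)
    tau = t_start + k * step
    tau = tau[tau <= t_end + 1e-12]
    if trains.breaks:
        keep = np.ones(len(tau), dtype=bool)
        for s, e in trains.breaks:
            keep &= ~((tau > s) & (tau < e))
        tau = tau[keep]
    phases = np.empty((len(tau), trains.n_neurons))
    for i, t in enumerate(trains.times):
        idx = np.searchsorted(t, tau, side="right") - 1
        idx = np.clip(idx, 0, len(t) - 2)
        t0 = t[idx]
        t1 = t[idx + 1]
        phases[:, i] = np.clip((tau - t0) / (t1 - t0), 0.0, 1.0 - 1e-12)
    return PhaseSeries(t=tau, phases=phases)


def instantaneous_splayness(phases: np.ndarray) -> np.ndarray:
    """gamma_k in [0, 1] for each row of phases (K, N): 0 = perfect splay."""
    n = phases.shape[1]
    srt = np.sort(phases, axis=1)
    psi = np.diff(srt, axis=1)
    closure = 1.0 - psi.sum(axis=1)
    psi = np.column_stack([psi, closure])
    gamma = n / (n - 1) * ((psi - 1.0 / n) ** 2).sum(axis=1)
    return gamma


def splayness(trains: SpikeTrains | PhaseSeries, step: float = GRID_STEP_S) -> float:
    """Time-averaged splayness s = 1 - sqrt(mean_k gamma_k), in [0, 1]."""
    ps = trains if isinstance(trains, PhaseSeries) else interpolate_phases(trains, step)
    gamma = instantaneous_splayness(ps.phases)
    return float(1.0 - np.sqrt(gamma.mean()))


def pair_sync_index(train_a, train_b=None, step: float = GRID_STEP_S) -> float:
    """Time-averaged two-neuron Kuramoto order parameter r in [0, 1]."""
    if train_b is not None:
        trains = SpikeTrains([np.asarray(train_a), np.asarray(train_b)])
    elif isinstance(train_a, SpikeTrains):
        if train_a.n_neurons != 2:
            raise ValueError("pair_sync_index needs exactly two trains")
        trains = train_a
    else:
        raise ValueError("provide two trains or a 2-neuron SpikeTrains")
    ps = interpolate_phases(trains, step)
    z = np.exp(2j * np.pi * ps.phases)
    r_k = np.abs(z.mean(axis=1))
    return float(r_k.mean())


def phase_histogram(reference: np.ndarray, other: np.ndarray, bins: int = 100,
                    trim: float = 3.0, centered: bool = False,
                    span: tuple | None = None):
    """Relative occurrence of ``other`` spikes within reference ISIs.

    Each reference ISI is normalized to phase [0, 1) and the other neuron's
    spikes are binned by phase; counts are normalized to sum to 1.  The
    first and last ``trim`` seconds of the record are discarded.  With
    ``centered=True`` the upper half is shifted to (-0.5, 0] so the
    histogram spans (-0.5, 0.5] around the reference spike.

    Returns (bin_centers, relative_occurrence).
    """
    reference = np.asarray(reference, dtype=float)
    other = np.asarray(other, dtype=float)
    if span is None:
        lo = min(reference[0], other[0]) + trim
        hi = max(reference[-1], other[-1]) - trim
    else:
        lo, hi = span[0] + trim, span[1] - trim
    ref = reference[(reference >= lo) & (reference <= hi)]
    oth = other[(other >= lo) & (other <= hi)]
    if len(ref) < 2 or len(oth) == 0:
        raise ValueError("no overlapping spikes after trimming")
    idx = np.searchsorted(ref, oth, side="right") - 1
    ok = (idx >= 0) & (idx <= len(ref) - 2)
    idx = idx[ok]
    ev = oth[ok]
    phi = (ev - ref[idx]) / (ref[idx + 1] - ref[idx])
    b = np.floor(phi * bins).astype(int) % bins
    counts = np.bincount(b, minlength=bins).astype(float)
    if counts.sum() == 0:
        raise ValueError("no events fall into reference ISIs")
    rel = counts / counts.sum()
    if centered:
        half = bins // 2
        rel = np.concatenate([rel[half:], rel[:half]])
        centers = (np.arange(bins) - half + 0.5) / bins
    else:
        centers = (np.arange(bins) + 0.5) / bins
    return centers, rel


def dip_fraction(centers: np.ndarray, rel: np.ndarray,
                 window: tuple = (-0.1, 0.1)) -> float:
    """Fraction of a centered pairwise histogram within ``window``.

    0.2 is the flat-histogram expectation for the default window; values
    well below it indicate out-of-phase (splayed) firing of the pair.
    """
    m = (centers > window[0]) & (centers < window[1])
    return float(rel[m].sum())


def sequence_statistics(trains: SpikeTrains, min_cycles: int = 10) -> dict:
    """Distribution of MN1-4 firing orders over the six cyclic classes.

    A cycle is one ISI of MN1; cycles that do not contain exactly one spike
    of each of MN2-4 are counted as 'irregular' and excluded from the
    six-class normalization.
    """
    if trains.n_neurons < 4:
        raise ValueError("sequence statistics need MN1-4")
    t1 = trains[0]
    if len(t1) < 2:
        raise ValueError("MN1 needs at least 2 spikes")
    counts = {c: 0 for c in SEQUENCE_CLASSES}
    irregular = 0
    total = 0
    others = [trains[i] for i in (1, 2, 3)]
    for a, b in zip(t1[:-1], t1[1:]):
        total += 1
        inside = []
        ok = True
        for label, t in zip("234", others):
            sel = t[(t >= a) & (t < b)]
            if len(sel) != 1:
                ok = False
                break
            inside.append((sel[0], label))
        if not ok:
            irregular += 1
            continue
        inside.sort()
        counts["1" + "".join(lbl for _, lbl in inside)] += 1
    n_ok = sum(counts.values())
    if total < min_cycles or (n_ok == 0 and irregular == total):
        if total < min_cycles:
            raise ValueError(f"only {total} cycles; need >= {min_cycles}")
    probs = {c: (counts[c] / n_ok if n_ok else np.nan) for c in SEQUENCE_CLASSES}
    return {"probabilities": probs, "counts": counts,
            "n_cycles": total, "n_irregular": irregular}


def isi_cv(train) -> float:
    """Coefficient of variation of the inter-spike intervals."""
    t = np.asarray(train, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 spikes")
    isi = np.diff(t)
    if len(isi) < 10:
        raise ValueError("need at least 10 ISIs")
    return float(isi.std(ddof=0) / isi.mean())


def compare_index_sets(group_a, group_b):
    """Two-sided Mann-Whitney U test between two sets of indices.

    Returns (U, p) with U the statistic of ``group_a``; ties use midranks.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    res = _sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
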