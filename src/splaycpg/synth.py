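"""Synthetic spike-train generator with known ground truth.

Emulates the statistical structure of multi-MN flight recordings without a
simulator: N periodic base trains at a common rate, with configurable
phase offsets (perfect splay, perfect synchrony, or explicit), independent
Gaussian per-spike jitter, optional recording breaks, and biased cyclic
firing sequences (e.g. a preference for 1423 over the other five orders).
Every statistic in :mod:`splaycpg.stats` can be validated against the
configured ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stats import SEQUENCE_CLASSES
from .trains import SpikeTrains


@dataclass
class SynthConfig:
    """Ground-truth configuration of the generator.

    jitter is the per-spike Gaussian s.d. as a fraction of the period;
    offsets (mode='offsets') are phases in [0, 1) per neuron; breaks are
    (start_s, end_s) intervals removed from the record.
    """

    n_neurons: int = 5
    rate_hz: float = 8.0
    duration_s: float = 30.0
    mode: str = "splay"            # splay | sync | offsets
    offsets: tuple | None = None
    jitter: float = 0.0
    breaks: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if self.mode not in ("splay", "sync", "offsets"):
            raise ValueError("mode must be splay, sync or offsets")
        if self.mode == "offsets" and (self.offsets is None
                                       or len(self.offsets) != self.n_neurons):
            raise ValueError("mode 'offsets' needs one offset per neuron")


def _apply_breaks(times: np.ndarray, breaks) -> np.ndarray:
    for s, e in breaks:
        times = times[(times < s) | (times > e)]
    return times


def gen_trains(cfg: SynthConfig) -> SpikeTrains:
    """Generate jittered periodic trains with the configured offsets."""
    rng = np.random.default_rng(cfg.seed)
    T = 1.0 / cfg.rate_hz
    if cfg.mode == "splay":
        offsets = np.arange(cfg.n_neurons) / cfg.n_neurons
    elif cfg.mode == "sync":
        offsets = np.zeros(cfg.n_neurons)
    else:
        offsets = np.asarray(cfg.offsets, dtype=float)
    base = np.arange(0.0, cfg.duration_s, T)
    out = []
    for i in range(cfg.n_neurons):
        t = base + offsets[i] * T
        if cfg.jitter > 0:
            t = t + rng.normal(0.0, cfg.jitter * T, size=len(t))
        t = t[(t >= 0) & (t <= cfg.duration_s)]
        if np.any(np.diff(t) <= 0):
            warnings.warn(f"jitter inverted spike order of neuron {i}; re-sorting")
            t = np.sort(t)
            t = t[np.insert(np.diff(t) > 1e-9, 0, True)]
        t = _apply_breaks(t, cfg.breaks)
        out.append(t)
    return SpikeTrains(out, span=(0.0, cfg.duration_s), breaks=list(cfg.breaks))


def gen_sequenced_trains(cfg: SynthConfig, weights: dict) -> SpikeTrains:
    """Generate 5-neuron splay trains whose per-cycle MN2-4 order within
    MN1's ISI is drawn from ``weights`` over the six cyclic classes.

    MN1 anchors each cycle; the drawn order assigns MN2-4 to the splay
    slots at 1/5, 2/5, 3/5 of the period and MN5 sits at 4/5.
    """
    if cfg.n_neurons != 5:
        raise ValueError("sequenced trains are defined for 5 neurons")
    w = np.array([weights.get(c, 0.0) for c in SEQUENCE_CLASSES], dtype=float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    rng = np.random.default_rng(cfg.seed)
    T = 1.0 / cfg.rate_hz
    n_cycles = int(np.floor(cfg.duration_s / T))
    draws = rng.choice(len(SEQUENCE_CLASSES), size=n_cycles, p=w)
    times: list[list[float]] = [[] for _ in range(5)]
    for c in range(n_cycles):
        t0 = c * T
        times[0].append(t0)
        order = SEQUENCE_CLASSES[draws[c]]       # e.g. "1423"
        for slot, ch in enumerate(order[1:], start=1):
            times[int(ch) - 1].append(t0 + slot * T / 5.0)
        times[4].append(t0 + 4.0 * T / 5.0)
    out = []
    for i, tl in enumerate(times):
        t = np.array(tl)
        if cfg.jitter > 0:
            t = np.sort(t + rng.normal(0.0, cfg.jitter * T, size=len(t)))
        t = _apply_breaks(t[(t >= 0) & (t <= cfg.duration_s)], cfg.breaks)
        out.append(t)
    return SpikeTrains(out, span=(0.0, cfg.duration_s), breaks=list(cfg.breaks))
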