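"""Conversion between gap-junction conductance and coupling coefficient.

In the passive regime (membrane hyperpolarized enough that all
voltage-gated channels are closed) a two-neuron gap-junction pair obeys

    CC = g_gap / (g_gap + g_L)

where CC is the steady-state ratio of post- to presynaptic voltage
deflection.  ``cc_measure_sim`` verifies this with the three-neuron
protocol: neuron 1 coupled to neuron 2, neuron 3 uncoupled as reference;
n1 receives I_base, n2 receives I_base + dI, and CC = (v1-v3)/(v2-v3) at
steady state, averaged over a grid of perturbation currents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .neuron import MNParameters, resting_state


def cc_analytic(g_gap: float, g_L: float) -> float:
    """Passive coupling coefficient for conductances in matching units."""
    if g_L <= 0:
        raise ValueError("g_L must be positive")
    if g_gap < 0:
        raise ValueError("g_gap must be non-negative")
    return g_gap / (g_gap + g_L)


def g_gap_from_cc(cc: float, g_L: float) -> float:
    """Invert CC = g_gap/(g_gap + g_L) to a gap conductance."""
    if not 0 <= cc < 1:
        raise ValueError("CC must lie in [0, 1)")
    if g_L <= 0:
        raise ValueError("g_L must be positive")
    return cc * g_L / (1.0 - cc)


@dataclass(frozen=True)
class CCProtocolConfig:
    """Three-neuron simulation protocol settings (currents in pA)."""

    I_base: float = -150.0
    dI_grid: tuple = (-5.0, -2.5, 2.5, 5.0)
    settle_ms: float = 400.0
    steady_tol: float = 1e-6     # mV/ms over the last check window
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.I_base >= 0:
            raise ValueError("I_base must be below rheobase (negative)")


def cc_measure_sim(params: MNParameters, g_gap: float,
                   protocol: CCProtocolConfig | None = None) -> float:
    """Simulated coupling coefficient of a gap-coupled pair (g_gap in nS).

    Raises if any neuron fires during the protocol (I_base too high).
    """
    pr = protocol or CCProtocolConfig()
    rest = resting_state(params, 0.0)
    G = np.zeros((3, 3))
    G[0, 1] = G[1, 0] = float(g_gap)
    p = params.to_vector()
    ccs = []
    for dI in pr.dI_grid:
        if dI == 0:
            continue
        I = np.array([pr.I_base, pr.I_base + dI, pr.I_base], dtype=float)
        v0 = np.full(3, rest.v)
        b0 = np.full(3, rest.b)
        h0 = np.full(3, rest.h)
        n_steps = int(round(pr.settle_ms / pr.dt))
        spikes, counts, vf, bf, hf, rec, fail = _kernels.integrate(
            p, G, I, v0, b0, h0, pr.dt, n_steps, 0.0, 0,
            _kernels.METHOD_RK4, 0)
        if fail >= 0:
            raise RuntimeError("integration failure during CC protocol")
        if counts.sum() > 0:
            raise RuntimeError("neuron fired during CC protocol; lower I_base")
        # steady-state check: one more short integration must not move v
        spikes2, _, vf2, _, _, _, _ = _kernels.integrate(
            p, G, I, vf.copy(), bf.copy(), hf.copy(), pr.dt,
            int(100.0 / pr.dt), 0.0, 0, _kernels.METHOD_RK4, 0)
        if np.max(np.abs(vf2 - vf)) / 100.0 > pr.steady_tol:
            raise RuntimeError("CC protocol did not reach steady state")
        v1, v2, v3 = vf2
        ccs.append((v1 - v3) / (v2 - v3))
    return float(np.mean(ccs))
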