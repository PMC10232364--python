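"""Phase-response curves and gap-junction coupling functions.

The PRC Z(phi) is computed by direct perturbation: an instantaneous voltage
kick of amplitude ``dv`` is applied at phase ``phi`` of the tonic-spiking
limit cycle and the asymptotic spike-time advance (in phase units, measured
at the third subsequent spike to let the trajectory relax back to the
cycle) is divided by ``dv``.

For two neurons coupled by a non-rectifying gap junction with uniform spike
waveforms, averaging over one period yields the interaction

    G(psi) = integral_0^1 Z(phi) * g_gap * (v(phi - psi) - v(phi)) / C_m dphi

as a function of the phase difference psi.  The odd part
G_odd(psi) = G(psi) - G(-psi) governs the slow phase-difference dynamics
``d psi/dt = nu + G_odd(psi)``; its stable zeros (negative slope) are the
locked phase relations of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neuron import LimitCycle, MNParameters, MNState, _integrate_single


@dataclass(frozen=True)
class PRC:
    """Phase-response curve on a uniform phase grid in [0, 1)."""

    phases: np.ndarray
    Z: np.ndarray          # phase advance per mV
    dv: float              # perturbation amplitude used (mV)
    cycle: LimitCycle

    def odd_part(self) -> np.ndarray:
        """Z_odd(phi) = (Z(phi) - Z(-phi)) / 2 on the same grid."""
        return (self.Z - _reverse_periodic(self.Z)) / 2.0


@dataclass(frozen=True)
class CouplingFunction:
    """Averaged pairwise gap-junction interaction G(psi) and its odd part."""

    psi: np.ndarray
    G: np.ndarray          # 1/ms
    g_gap: float           # nS
    C_m: float             # pF

    @property
    def G_odd(self) -> np.ndarray:
        return self.G - _reverse_periodic(self.G)


def _reverse_periodic(y: np.ndarray) -> np.ndarray:
    """y(-x) on a uniform periodic grid with x_0 = 0."""
    out = np.empty_like(y)
    out[0] = y[0]
    out[1:] = y[:0:-1]
    return out


def compute_prc(params: MNParameters, I_in: float, dv: float = 0.5,
                n_phases: int = 64, cycle: LimitCycle | None = None,
                n_spike: int = 3, dt: float = 0.01) -> PRC:
    """Direct-perturbation PRC at input current ``I_in``.

    ``n_spike`` is the spike index at which the asymptotic phase shift is
    read off (the first spikes still carry relaxation transients).
    """
    from .neuron import find_limit_cycle

    if cycle is None:
        cycle = find_limit_cycle(params, I_in, dt=dt)
    if abs(cycle.I_in - I_in) > 1e-9:
        raise ValueError("cycle was computed at a different input current")
    T = cycle.period
    phases = np.arange(n_phases) / n_phases
    Z = np.empty(n_phases)
    horizon = (n_spike + 1.5) * T
    for k, phi in enumerate(phases):
        st = cycle.state_at_phase(phi)
        pert = MNState(v=st.v + dv, b=st.b, h=st.h)
        sp, _, _ = _integrate_single(params, I_in, pert, horizon, dt)
        if len(sp) < n_spike:
            Z[k] = np.nan
            continue
        # unperturbed: spikes at (1-phi)T, (2-phi)T, ... from phase phi
        t_unpert = (n_spike - phi) * T
        t_pert = sp[n_spike - 1]
        Z[k] = (t_unpert - t_pert) / T / dv
    return PRC(phases=phases, Z=Z, dv=dv, cycle=cycle)


def coupling_function(prc: PRC, cycle: LimitCycle | None = None,
                      g_gap: float = 0.0435, C_m: float | None = None) -> CouplingFunction:
    """Averaged coupling function G(psi) from a PRC and the cycle waveform.

    ``g_gap`` in nS.  Uses the uniform-spike-waveform assumption: both
    neurons follow the same uncoupled limit-cycle voltage v(phi).
    """
    if cycle is None:
        cycle = prc.cycle
    if abs(cycle.I_in - prc.cycle.I_in) > 1e-9:
        raise ValueError("PRC and cycle must be computed at the same input current")
    if C_m is None:
        C_m = cycle.params.C_m
    n = len(prc.phases)
    v = np.interp(prc.phases, cycle.phases, cycle.states[:, 0], period=1.0)
    Z = prc.Z
    G = np.empty(n)
    for m in range(n):
        v_shift = np.roll(v, m)        # v(phi - psi_m) on the matched grid
        G[m] = np.mean(Z * g_gap * (v_shift - v) / C_m)
    return CouplingFunction(psi=prc.phases.copy(), G=G, g_gap=g_gap, C_m=C_m)


def fixpoints(cf: CouplingFunction, nu: float = 0.0,
              min_grid: int = 256) -> list[tuple[float, str]]:
    """Zeros of nu + G_odd(psi) with their stability.

    Returns (psi*, 'stable'|'unstable') sorted by psi; stability is a
    negative local slope of nu + G_odd.  If |nu| exceeds max|G_odd| the
    pair drifts and the list is empty.
    """
    psi = cf.psi
    g_odd = cf.G_odd
    if len(psi) < min_grid:
        fine = np.arange(min_grid) / min_grid
        g_odd = np.interp(fine, psi, g_odd, period=1.0)
        psi = fine
    f = nu + g_odd
    n = len(psi)
    out = []
    for i in range(n):
        j = (i + 1) % n
        fi, fj = f[i], f[j]
        if fi == 0.0 and fj != 0.0:
            root = psi[i]
        elif fi * fj < 0:
            # linear interpolation within the cell (periodic wrap)
            dx = 1.0 / n
            root = (psi[i] + dx * fi / (fi - fj)) % 1.0
        else:
            continue
        slope = (fj - fi) * n
        out.append((float(root), "stable" if slope < 0 else "unstable"))
    # dedupe near-identical roots
    dedup: list[tuple[float, str]] = []
    for r, s in sorted(out):
        if not dedup or min(abs(r - dedup[-1][0]), 1 - abs(r - dedup[-1][0])) > 2.0 / n:
            dedup.append((r, s))
    return dedup


def iterated_map(psi_grid: np.ndarray, Z_odd: np.ndarray, psi0: float,
                 n_iter: int = 200, tol: float = 1e-6):
    """Iterate the return map psi_{n+1} = psi_n + Z_odd(psi_n) (mod 1).

    Returns (trajectory, verdict) with verdict the fixpoint reached (float)
    or 'drift' if the iteration did not settle.
    """
    traj = np.empty(n_iter + 1)
    traj[0] = psi0 % 1.0
    for k in range(n_iter):
        z = np.interp(traj[k], psi_grid, Z_odd, period=1.0)
        traj[k + 1] = (traj[k] + z) % 1.0
    d = abs(traj[-1] - traj[-2])
    d = min(d, 1 - d)
    verdict = float(traj[-1]) if d < tol else "drift"
    return traj, verdict
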