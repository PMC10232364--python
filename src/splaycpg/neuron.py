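"""Single-compartment conductance-based flight motoneuron (MN) model.

The model is three-dimensional: membrane voltage ``v``, the Shab delayed
rectifier activation gate ``b`` and the Na channel inactivation gate ``h``.
Na activation ``m`` is instantaneous (``m = m_inf(v)``).  The currents are

    I_L    = g_L (v - E_L)
    I_shab = g_shab b^4 (v - E_K)
    I_Na   = g_Na m_inf(v)^3 (1 - h) (v - E_Na)

and the current balance reads ``C_m dv/dt = I_in - I_L - I_shab - I_Na + I_gap``.
Gates relax with first-order kinetics ``tau_x(v) dx/dt = x_inf(v) - x``.

Note on the inactivation convention: ``h`` is the inactivation *level* (it
grows with depolarization, half-level at v_half_h) and the channel
availability is ``1 - h``; the classical, monotonically decreasing
"steady-state inactivation curve" is therefore ``1 - h_inf(v)``.

Steady-state curves are Boltzmann sigmoids in the thermal-voltage
parameterization ``x_inf(v) = logistic(z_x Q (v - v_half_x))`` with the
gating charge ``z_x`` and ``Q = e/(k_B T) ~= 39.2 / V``.  Gate time
constants follow the thermodynamic bell form
``tau_x(v) = tau_x_min + tau_x_amp / cosh(z_x Q (v - v_half_x) / 2)``.

Internal units: mV, ms, pA, pF, nS (1 nS * 1 mV = 1 pA; 1 pF/1 nS = 1 ms).

Depolarizing the Shab conductance axis moves the spike-onset bifurcation of
the model through three excitability classes: saddle-homoclinic-orbit (HOM)
at low g_shab, saddle-node-on-invariant-circle (SNIC) at intermediate
g_shab and a subcritical Hopf (fold-of-limit-cycles) onset at high g_shab.
``classify_excitability`` determines the class operationally from onset
firing rate and rest/limit-cycle bistability instead of numerical
continuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from . import _kernels

#: thermal voltage factor e/(k_B T) in 1/mV (~39.2 per volt)
Q_THERMAL = 0.0392

#: leak conductance (nS) pinned by the passive coupling-coefficient anchor
#: CC = g_gap/(g_gap + g_L) with CC = 0.005 at g_gap = 43.5 pS
G_LEAK_NS = 0.0435 * (1.0 - 0.005) / 0.005 * 1e-3 * 1e3  # = 8.6565 nS


@dataclass(frozen=True)
class MNParameters:
    """Biophysical parameters of one motoneuron.

    Conductances in nS, voltages in mV, capacitance in pF, times in ms.
    Defaults are the calibrated flight-MN values; ``g_shab`` defaults to the
    low-Shab (SNL-regime) operating point.
    """

    C_m: float = 60.0          # pF, passive tau = C_m/g_L ~ 6.9 ms
    g_L: float = G_LEAK_NS     # nS
    E_L: float = -60.0         # mV
    g_Na: float = 431.2        # nS
    E_Na: float = 55.0         # mV
    g_shab: float = 137.68216  # nS
    E_K: float = -72.0         # mV
    v_half_m: float = -33.0    # mV
    v_half_h: float = -39.14   # mV (inactivation level half-voltage)
    v_half_b: float = -42.14   # mV
    z_m: float = 2.7           # Na activation gating charge
    z_h: float = 4.25          # Na inactivation gating charge
    z_b: float = 3.0           # Shab activation gating charge
    tau_b_amp: float = 0.5     # ms
    tau_b_min: float = 0.5     # ms
    tau_h_amp: float = 2.0     # ms
    tau_h_min: float = 0.5     # ms
    Q: float = Q_THERMAL       # 1/mV
    zt_b: float = 0.0          # tau_b bell width charge (0 -> use z_b)
    zt_h: float = 0.0          # tau_h bell width charge (0 -> use z_h)

    def __post_init__(self) -> None:
        if not (self.g_L >= 0 and self.g_Na >= 0 and self.g_shab >= 0):
            raise ValueError("conductances must be non-negative")
        if not self.E_Na > self.E_K:
            raise ValueError("requires E_Na > E_K")
        if not self.Q > 0:
            raise ValueError("thermal factor Q must be positive")
        if not self.C_m > 0:
            raise ValueError("capacitance must be positive")

    def to_vector(self) -> np.ndarray:
        """Flat float64 parameter vector consumed by the numba kernels."""
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=np.float64)


@dataclass(frozen=True)
class MNState:
    """Dynamical state (v, b, h) of one motoneuron."""

    v: float
    b: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.b <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError("gate variables must lie in [0, 1]")


@dataclass(frozen=True)
class LimitCycle:
    """Tonic-spiking limit cycle sampled on a uniform phase grid.

    Phase 0 is the spike time (upward 0 mV crossing).  ``states`` has shape
    (n_phases, 3) with columns (v, b, h); ``period`` in ms.
    """

    period: float
    phases: np.ndarray
    states: np.ndarray
    I_in: float
    params: MNParameters

    @property
    def rate_hz(self) -> float:
        """Intrinsic firing rate in Hz."""
        return 1000.0 / self.period

    def state_at_phase(self, phi: float) -> MNState:
        """Interpolate the cycle state at phase ``phi`` in [0, 1)."""
        phi = float(phi) % 1.0
        n = len(self.phases)
        x = phi * n
        i0 = int(math.floor(x)) % n
        i1 = (i0 + 1) % n
        w = x - math.floor(x)
        v, b, h = (1 - w) * self.states[i0] + w * self.states[i1]
        return MNState(v=float(v), b=float(min(max(b, 0.0), 1.0)), h=float(min(max(h, 0.0), 1.0)))


# ---------------------------------------------------------------------------
# gating curves and currents
# ---------------------------------------------------------------------------

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def steady_state_gates(v, params: MNParameters):
    """Steady-state gate values (m_inf, h_inf, b_inf) at voltage ``v``.

    ``m_inf`` and ``b_inf`` are activation curves (increasing in v);
    ``h_inf`` is the steady inactivation level (increasing in v) whose
    complement ``1 - h_inf`` is the decreasing availability curve.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")
    q = params.Q
    m_inf = _logistic(params.z_m * q * (v - params.v_half_m))
    h_inf = _logistic(params.z_h * q * (v - params.v_half_h))
    b_inf = _logistic(params.z_b * q * (v - params.v_half_b))
    return m_inf, h_inf, b_inf


def gate_time_constants(v, params: MNParameters):
    """Voltage-dependent gate time constants (tau_b, tau_h) in ms."""
    v = np.asarray(v, dtype=float)
    q = params.Q
    ztb = params.zt_b if params.zt_b > 0 else params.z_b
    zth = params.zt_h if params.zt_h > 0 else params.z_h
    tau_b = params.tau_b_min + params.tau_b_amp / np.cosh(
        ztb * q * (v - params.v_half_b) / 2.0)
    tau_h = params.tau_h_min + params.tau_h_amp / np.cosh(
        zth * q * (v - params.v_half_h) / 2.0)
    return tau_b, tau_h


def membrane_currents(state: MNState, params: MNParameters):
    """Ionic currents (I_L, I_shab, I_Na) in pA at the given state."""
    v = state.v
    m_inf, _, _ = steady_state_gates(v, params)
    i_l = params.g_L * (v - params.E_L)
    i_shab = params.g_shab * state.b ** 4 * (v - params.E_K)
    i_na = params.g_Na * float(m_inf) ** 3 * (1.0 - state.h) * (v - params.E_Na)
    return float(i_l), float(i_shab), float(i_na)


def derivatives(state: MNState, I_in: float, I_gap: float, params: MNParameters):
    """Time derivatives (dv/dt, db/dt, dh/dt) in (mV/ms, 1/ms, 1/ms)."""
    i_l, i_shab, i_na = membrane_currents(state, params)
    dv = (I_in - i_l - i_shab - i_na + I_gap) / params.C_m
    _, h_inf, b_inf = steady_state_gates(state.v, params)
    tau_b, tau_h = gate_time_constants(state.v, params)
    db = (float(b_inf) - state.b) / float(tau_b)
    dh = (float(h_inf) - state.h) / float(tau_h)
    return dv, db, dh


def resting_state(params: MNParameters, I_in: float = 0.0) -> MNState:
    """Stable resting fixed point (lowest-voltage root of the steady IV curve)."""
    from scipy.optimize import brentq

    def iv(v):
        m_inf, h_inf, b_inf = steady_state_gates(v, params)
        return (I_in
                - params.g_L * (v - params.E_L)
                - params.g_shab * b_inf ** 4 * (v - params.E_K)
                - params.g_Na * m_inf ** 3 * (1 - h_inf) * (v - params.E_Na))

    grid = np.linspace(-90.0, -20.0, 1401)
    vals = np.array([iv(v) for v in grid])
    sign = np.sign(vals)
    roots = np.where(np.diff(sign) != 0)[0]
    if len(roots) == 0:
        raise ValueError("no resting fixed point in [-90, -20] mV")
    i = roots[0]
    v0 = brentq(iv, grid[i], grid[i + 1])
    _, h_inf, b_inf = steady_state_gates(v0, params)
    return MNState(v=float(v0), b=float(b_inf), h=float(h_inf))


# ---------------------------------------------------------------------------
# limit-cycle detection and f-I analysis
# ---------------------------------------------------------------------------

class SubthresholdError(RuntimeError):
    """Raised when no sustained spiking is found at the requested input."""


def _integrate_single(params, I_in, state, duration_ms, dt=0.01, record_stride=0):
    """RK4-integrate one neuron; returns (spike_times_ms, final_state, traces)."""
    p = params.to_vector()
    v0 = np.array([state.v], dtype=np.float64)
    b0 = np.array([state.b], dtype=np.float64)
    h0 = np.array([state.h], dtype=np.float64)
    G = np.zeros((1, 1))
    I = np.array([float(I_in)])
    n_steps = int(round(duration_ms / dt))
    out = _kernels.integrate(p, G, I, v0, b0, h0, dt, n_steps, 0.0, 0,
                             _kernels.METHOD_RK4, record_stride)
    spikes, counts, vf, bf, hf, rec, fail = out
    if fail >= 0:
        raise RuntimeError(f"integration blow-up (|v|>200 mV) at step {fail}")
    st = MNState(v=float(vf[0]), b=float(min(max(bf[0], 0), 1)), h=float(min(max(hf[0], 0), 1)))
    return spikes[0, : counts[0]].copy(), st, rec


def find_limit_cycle(params: MNParameters, I_in: float, n_phases: int = 256,
                     dt: float = 0.01, max_time_ms: float = 20000.0,
                     tol: float = 1e-3) -> LimitCycle:
    """Locate the tonic-spiking limit cycle at input current ``I_in`` (pA).

    Integrates from a supra-threshold kicked state past the transient until
    the last five inter-spike intervals agree to ``tol`` (relative), then
    resamples one period onto a uniform phase grid anchored at the spike
    (phase 0 = upward 0 mV crossing).  Raises :class:`SubthresholdError`
    if spiking does not persist.
    """
    rest = resting_state(params, 0.0)
    kick = MNState(v=-20.0, b=rest.b, h=rest.h)
    chunk = 2000.0
    spikes_all = []
    state = kick
    t0 = 0.0
    period = None
    while t0 < max_time_ms:
        sp, state, _ = _integrate_single(params, I_in, state, chunk, dt)
        spikes_all.extend((sp + t0).tolist())
        t0 += chunk
        if len(spikes_all) >= 7:
            isi = np.diff(np.array(spikes_all[-7:]))
            if isi.max() - isi.min() < tol * isi.mean():
                period = float(isi[-5:].mean())
                break
        # no recent spike in the whole chunk -> died out
        if len(spikes_all) == 0 or spikes_all[-1] < t0 - chunk:
            raise SubthresholdError(
                f"no sustained spiking at I_in={I_in} pA (subthreshold)")
    if period is None:
        raise SubthresholdError(
            f"ISIs did not converge within {max_time_ms} ms at I_in={I_in} pA")

    # integrate a little over one period from the converged state, recording
    # finely, then re-anchor at the next spike and resample on the phase grid
    rec_dt = dt
    sp, _, rec = _integrate_single(params, I_in, state, 2.2 * period, dt,
                                   record_stride=1)
    if len(sp) < 2:
        raise SubthresholdError("lost the cycle while resampling")
    t_rec = np.arange(rec.shape[0]) * rec_dt
    t_spk = sp[0]
    phases = np.arange(n_phases) / n_phases
    samp_t = t_spk + phases * period
    states = np.empty((n_phases, 3))
    for c in range(3):
        states[:, c] = np.interp(samp_t, t_rec, rec[:, 0, c])
    return LimitCycle(period=period, phases=phases, states=states,
                      I_in=float(I_in), params=params)


def firing_rate(params: MNParameters, I_in: float, from_state: MNState | None = None,
                t_max_ms: float = 6000.0, t_discard_ms: float = 2000.0,
                dt: float = 0.01) -> float:
    """Sustained firing rate (Hz) from an initial state (default: rest).

    Returns 0.0 if no spikes occur after the discard window.
    """
    state = from_state if from_state is not None else resting_state(params, 0.0)
    sp, _, _ = _integrate_single(params, I_in, state, t_max_ms, dt)
    sp = sp[sp > t_discard_ms]
    if len(sp) < 3:
        return 0.0
    isi = np.diff(sp)
    return 1000.0 / float(np.mean(isi))


def rheobase(params: MNParameters, I_lo: float = 0.0, I_hi: float = 1500.0,
             rel_tol: float = 2e-3, probe_ms: float = 4000.0, dt: float = 0.01,
             from_cycle: bool = False) -> float:
    """Smallest input current (pA) producing sustained spiking.

    With ``from_cycle=True`` the probe is initialized from a spiking
    (kicked) state instead of rest, which detects the lower edge of the
    limit-cycle branch in bistable (HOM / subcritical-Hopf) regimes.
    """
    rest = resting_state(params, 0.0)
    init = MNState(v=-20.0, b=rest.b, h=rest.h) if from_cycle else rest

    def spikes_at(I):
        sp, _, _ = _integrate_single(params, I, init, probe_ms, dt)
        return len(sp[sp > probe_ms / 2]) >= 3

    if spikes_at(I_lo):
        return I_lo
    # coarse upward scan first: at very high inputs the model can sit in
    # excitation block, so probing I_hi directly is not reliable
    grid = np.linspace(I_lo, I_hi, 31)[1:]
    hi = None
    for I in grid:
        if spikes_at(float(I)):
            hi = float(I)
            break
    if hi is None:
        raise SubthresholdError(f"no spiking up to {I_hi} pA")
    lo = max(I_lo, hi - (grid[1] - grid[0]))
    while (hi - lo) > rel_tol * max(abs(hi), 1.0):
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return hi


def f_I_curve(params: MNParameters, I_grid, dt: float = 0.01,
              t_max_ms: float = 6000.0) -> list[tuple[float, float]]:
    """Firing rate (Hz) versus injected current (pA), starting from rest."""
    I_grid = np.asarray(I_grid, dtype=float)
    if np.any(np.diff(I_grid) < 0):
        raise ValueError("I_grid must be sorted ascending")
    out = []
    for I in I_grid:
        out.append((float(I), firing_rate(params, float(I), t_max_ms=t_max_ms, dt=dt)))
    return out


def cycle_floor(params: MNParameters, I_start: float | None = None,
                step_frac: float = 0.005, probe_ms: float = 1500.0,
                dt: float = 0.01, max_steps: int = 120):
    """Continuation descent along the limit-cycle branch.

    Starting just above the rest rheobase, the input current is reduced in
    small relative steps while re-using the running state, until sustained
    spiking is lost.  Returns (I_floor, rate_at_floor): the lowest current
    with a persistent cycle and the firing rate there.  In bistable (HOM /
    fold-of-limit-cycles) regimes I_floor lies below the rest rheobase.
    """
    if I_start is None:
        I_start = rheobase(params, dt=dt, probe_ms=2000.0) * 1.02
    rest = resting_state(params, 0.0)
    state = MNState(-20.0, rest.b, rest.h)
    I = float(I_start)
    sp, state, _ = _integrate_single(params, I, state, 2000.0, dt)
    if len(sp[sp > 1000.0]) < 3:
        raise SubthresholdError(f"no cycle at descent start I={I_start:.3f} pA")
    last_rate = np.nan
    for _ in range(max_steps):
        I_next = I * (1.0 - step_frac)
        sp, st2, _ = _integrate_single(params, I_next, state, probe_ms, dt)
        late = sp[sp > probe_ms / 2]
        if len(late) < 3:
            return I, last_rate
        I, state = I_next, st2
        last_rate = 1000.0 / float(np.mean(np.diff(late)))
    return I, last_rate


def onset_rate(params: MNParameters, dt: float = 0.01) -> float:
    """Minimum sustained firing rate at spiking onset (Hz).

    Walks down the limit-cycle branch to its lower edge (``cycle_floor``)
    and reports the rate there.  For SNIC onsets this is arbitrarily low
    (probe-resolution limited); for homoclinic or fold-of-limit-cycle
    (subcritical Hopf) onsets it is finite.
    """
    I_rest = rheobase(params, dt=dt, probe_ms=2000.0)
    _, rate = cycle_floor(params, I_rest * 1.02, dt=dt)
    if not np.isfinite(rate):
        rate = firing_rate(params, I_rest * 1.01, t_max_ms=10000.0,
                           t_discard_ms=4000.0, dt=dt)
    return float(rate)


def classify_excitability(params: MNParameters, hopf_rate_hz: float = 20.0,
                          bistable_frac: float = 0.01, dt: float = 0.01) -> str:
    """Operational excitability class: 'HOM', 'SNIC' or 'Hopf'.

    Decision procedure: (i) if the minimum sustained firing rate at spiking
    onset exceeds ``hopf_rate_hz`` the onset is a subcritical Hopf /
    fold-of-limit-cycles ('Hopf'); otherwise (ii) if the limit-cycle branch
    extends below the rest rheobase by more than ``bistable_frac`` (the
    resting state coexists with the cycle) the onset is saddle homoclinic
    ('HOM'); else it is a SNIC.
    """
    try:
        I_rest = rheobase(params, dt=dt, probe_ms=2000.0)
    except SubthresholdError as exc:
        raise SubthresholdError("unclassifiable: no spiking in scanned range") from exc
    I_floor, rate = cycle_floor(params, I_rest * 1.02, dt=dt)
    if np.isfinite(rate) and rate > hopf_rate_hz:
        return "Hopf"
    if (I_rest - I_floor) / I_rest > bistable_frac:
        return "HOM"
    return "SNIC"
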