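# Methods

## Model

Each motoneuron (MN) is a single compartment with three state variables:
membrane voltage `v`, the Shab delayed-rectifier activation gate `b`
(fourth power in the current) and the Na⁺ inactivation gate `h`; Na⁺
activation `m` is instantaneous. The current balance and gate kinetics are

    C_m dv/dt = I_in − g_L (v − E_L) − g_shab b⁴ (v − E_K)
                − g_Na m_∞(v)³ (1 − h)(v − E_Na) + Σ_j g_gap^{ij} (v_j − v_i)
    τ_b(v) db/dt = b_∞(v) − b,      τ_h(v) dh/dt = h_∞(v) − h.

`h` is the inactivation *level*: `h_∞` increases with depolarization (half
level at −39.14 mV) and the channel availability is `1 − h`; the classical
decreasing steady-state inactivation curve is `1 − h_∞(v)`. Steady-state
curves are Boltzmann sigmoids in the thermal-voltage parameterization,
`x_∞(v) = σ(z_x Q (v − v_x))` with `Q = e/(k_B T) ≈ 39.2 /V`, and the gate
time constants follow the thermodynamic bell
`τ_x(v) = τ_x,min + τ_x,amp / cosh(z_x Q (v − v_x)/2)`.

Gap junctions are linear, bidirectional and non-rectifying,
`I_gap^{ij} = g_gap^{ij}(v_j − v_i)`, so the total gap current over all
ordered pairs vanishes identically for any symmetric coupling matrix.

## Parameters

Fixed biophysical constants: `g_Na = 431.2 nS`, `E_Na = 55 mV`,
`E_K = −72 mV`, half-voltages `v_m = −33 mV`, `v_h = −39.14 mV`,
`v_b = −42.14 mV`, `Q = 39.2 /V`, and `g_shab` spanning 137.68–344.96 nS
across the excitability presets.

The leak conductance is pinned by the passive coupling-coefficient
relation `CC = g_gap/(g_gap + g_L)`: requiring `CC = 0.005` at
`g_gap = 43.5 pS` gives `g_L = 8.6565 nS`, which simultaneously yields
`CC = 0.257` at 3 nS — the two anchors of the weak/strong coupling
conditions. This leaves the gate slopes, the τ amplitudes, `C_m` and
`E_L` as the free kinetics. They were calibrated once, jointly, so that:

* the resting potential without input is ≈ −60 mV (calibrated −58.8 mV);
* the spike-onset bifurcation traverses HOM → SNL → SNIC → subcritical
  Hopf as `g_shab` is raised;
* the high-Shab (344.96 nS) onset has a finite minimum sustained rate of
  ≈ 47 Hz;
* the low-Shab neuron's phase-response curve (PRC) is asymmetric with a
  negative slope around phase 0.5, so that weak gap junctions lock pairs
  in antiphase and the five-neuron network splays.

The calibrated values are `z_m = 2.7`, `z_h = 4.25`, `z_b = 3.0`,
`τ_b = 0.5 + 0.5/cosh ms`, `τ_h = 0.5 + 2.0/cosh ms`, `C_m = 60 pF`,
`E_L = −60 mV`. Mechanistically, the splay-capable regime requires (i) a
shallow Na⁺ activation curve, so the window current creates the
saddle-node structure at low voltage where the steep Shab gate is still
closed, and (ii) fast gate kinetics, so the post-spike trajectory
re-enters close to the saddle and the neuron spends the slow part of its
cycle *early*, skewing the PRC peak to early phases. Slower Shab kinetics
or a shallower Shab activation curve strengthen the delayed negative
feedback at the resting state and produce the oscillatory (Hopf) onset at
high `g_shab`.

One known compromise: with this single frozen kinetics set the small-SNL
point sits near `g_shab ≈ 110 nS`, so the nominal low-Shab operating
point (137.68 nS) lies just on the SNIC side of it — the antiphase-locking
PRC shape is preserved there, but rest/limit-cycle bistability (the
operational HOM signature) appears only below ≈ 110 nS, which is where the
`HOM` preset probes it. Joint tuning showed that pushing the bistable
window up to 137.68 nS and holding the 47 Hz Hopf onset pull the Shab time
constant in opposite directions under the pinned leak and printed
half-voltages; the network-level anchors were given priority.

Excitability classification is operational rather than by numerical
continuation: walk the limit-cycle branch downward in current
(continuation descent, 0.5 % steps, 1.5 s probes); if the minimum
sustained rate at the branch floor exceeds 20 Hz the onset is
Hopf/fold-of-limit-cycles; else if the branch floor lies > 1 % below the
rest rheobase (bistability) the onset is homoclinic; else SNIC.

## Network simulations

Presets for the coupling matrix: homogeneous 43.5 pS; heterogeneous with
MN1–MN2 and MN3–MN4 at 86.59 pS, every MN5 connection at 27.19 pS (half
the mean of the others) and the remaining pairs at 38.27 pS — same grand
mean as the homogeneous case; strong 3 nS. Stochastic runs use the Heun
predictor–corrector with the same Wiener increment in both stages and an
additive zero-mean white-noise current of σ = 0.949 pA√ms per neuron;
deterministic runs use classical RK4. Default steps: 20 µs (stochastic
desk profile; the paper-scale profile uses 3 µs), 100 µs (deterministic).
Spikes are detected as upward 0 mV crossings with a 2 ms refractory window
and linearly interpolated crossing times, which decouples spike times from
the step size (halving dt moves spike times of a 1 s run by < 0.1 ms).
Neurons start at independent uniformly random phases of the uncoupled
limit cycle; all randomness is seeded.

Operating currents per preset are fixed at values giving uncoupled rates
in the working range of flight (SNL 18.3 pA → 14.9 Hz, SNIC 22 pA →
12.5 Hz); gap-junction load shifts the coupled rates slightly, and no
frequency homeostasis is applied, so intermediate coupling strengths may
drift in rate.

## Phase reduction

PRCs are computed by direct perturbation: an instantaneous voltage kick
(default 0.5 mV, in the linear regime — halving the kick changes Z by a
few per cent) is applied at each of 64 grid phases and the induced spike
advance is read at the third subsequent spike to skip the relaxation
transient, in units of phase per mV. The coupling function assumes
uniform spike waveforms (both neurons run on the uncoupled cycle) and is
evaluated by the periodic trapezoid (mean) rule on the matched phase
grid, so `G^odd(0) = G^odd(0.5) = 0` holds to rounding. Fixpoints of
`ν + G^odd` are located by sign change with linear interpolation on a
≥ 256-point grid; stability is a negative local slope. Predictions are
cross-checked by two-neuron simulations, which lock within 0.05 of the
predicted phase difference.

## Statistics

Phases are interpolated linearly between spikes on a common 1 ms grid
from the first spike of the last neuron to start to the last spike of the
first neuron to stop, with recording-break intervals omitted. The
splayness index compares the sorted cyclic phase gaps `ψ_{k,i}` (which
close to 1 by construction) to the perfect splay:
`γ_k = N/(N−1) Σ_i (ψ_{k,i} − 1/N)²` and `s = 1 − √(mean_k γ_k)`. The
pairwise synchronization index is the time average of
`r_k = |½ Σ_j e^{i2πφ_{k,j}}|`. Pairwise histograms normalize each
reference ISI to phase [0, 1), bin the other neuron's events into 100
bins (`floor(100 φ)`, phase 1 wraps to bin 0) and divide by the event
count; the centered variant moves the upper 50 bins in front, and the dip
fraction is the mass in (−0.1, 0.1) (0.2 under a flat histogram). For
simulator output the first 3 s are discarded as transient, mirroring the
3 s trim applied to recorded bouts. A firing cycle is one MN1 ISI;
cycles containing exactly one spike of each of MN2–4 are classified into
the six cyclic orders, others counted separately as irregular. Group
comparisons use the two-sided Mann–Whitney U test (midranks for ties),
uncorrected.

## Synthetic generator

`gen_trains` produces N periodic trains at a common rate with splay
(k/N), sync, or explicit offsets, plus independent Gaussian per-spike
jitter (s.d. as a fraction of the period) — independent jitter keeps the
expected rate exact and gives `ISI CV ≈ jitter·√2`. `gen_sequenced_trains`
draws each cycle's MN2–4 order from explicit weights over the six
classes. The generator reproduces splayness extremes exactly and
sequence weights within total-variation 0.05 at a few thousand cycles.
It emulates rhythmicity, splayness, jitter, breaks and sequence bias of
in-flight recordings but not slow rate drift, bout structure or
recording noise, so passing statistics tests validates the estimators,
not the biology of any particular recording.

## Calcium extrapolation

Each spike adds a peak-normalized difference of exponentials with
rise τ 6.2 ms and decay τ 82 ms (peak at 17.3 ms) to its fibre's trace,
on a 0.5 ms grid; fibre signals superpose linearly, and the population
trace averages the six DLM fibres (MN1–4 one fibre each, MN5 two). For
the wingbeat-stability prediction the idealized splay staggers the six
fibre transients uniformly (offsets k/6) and the fluctuation of the
steady-state population trace (after a 2 s warm-up) is measured
peak-to-trough; in the isolated-transient limit the sync/splay ratio then
equals the fibre count (6), and at the in-flight rate of 5 Hz temporal
summation raises it to ≈ 9.5 — the "about eightfold" regime. The
temporal-s.d. metric and the strict motor-unit splay (five phases, MN5's
fibres co-timed, ratio ≈ 4.7 at 5 Hz) are available as options. Since
wingbeat frequency is taken proportional to the population calcium
level, the calcium ratio is reported as the wingbeat-power fluctuation
ratio.

## Problem sizes and numerics

Stochastic acceptance-level quantifications use 10 replicates of 30 s at
dt = 20 µs (the desk profile; a paper-scale profile with 60 s and 3 µs is
provided); the coupling-coefficient sweep uses 23 s runs on a reduced CC
grid; sequence preference uses 5 × 120 s runs. Limit-cycle location
requires the last ISIs to agree within 0.1 %; the CC protocol declares
steady state when a further 100 ms moves the voltage by < 10⁻⁶ mV/ms.
Blow-ups (|v| > 200 mV) raise errors naming the step. Degenerate inputs
(neurons with < 2 spikes, empty histogram overlaps, sub-threshold drive)
raise descriptive errors rather than returning NaNs.

## Limitations

The gate kinetics are a calibrated stand-in constrained by printed
half-voltages, conductances and behavioural anchors, not fits to
channel recordings; absolute currents and time constants should not be
over-interpreted. The phase reduction is first order and assumes weak
coupling; it is not valid in the strong-coupling regime (there the full
simulation is authoritative). Network size is generic in the code but
all presets and statistics target N = 5.
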