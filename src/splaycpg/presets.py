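"""Excitability-regime presets of the flight-MN model.

Each preset fixes the Shab conductance (the axis along which the
spike-onset bifurcation changes class) and a network operating current
chosen so the uncoupled neuron fires in the working range of flight
(~12-15 Hz; deep-HOM cycles do not reach that band and run faster).

``SNL`` is the low-Shab operating point used for all splay-state network
simulations: it lies near the small saddle-node-loop point, where the PRC
is asymmetric with a negative slope around phase 0.5 and weak gap-junction
coupling locks pairs in antiphase.  ``HOM`` probes the bistable
saddle-homoclinic regime below the SNL point, ``SNIC`` the intermediate
regime (synchronizing) and ``Hopf`` the high-Shab regime with a finite
(~47 Hz) onset rate.
"""

from __future__ import annotations

from dataclasses import replace

from .neuron import MNParameters

#: printed bounds of the Shab conductance range (nS)
G_SHAB_LOW = 137.68216
G_SHAB_HIGH = 344.96

#: (g_shab [nS], I_in [pA]) per regime; currents are calibrated operating
#: points (see docs/methods.md)
PRESETS = {
    "HOM": (90.0, 12.0),
    "SNL": (G_SHAB_LOW, 18.3),
    "SNIC": (230.0, 22.0),
    "Hopf": (G_SHAB_HIGH, 61.5),
}


def preset_params(name: str, **overrides) -> MNParameters:
    """MNParameters for a named excitability preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    g_shab, _ = PRESETS[name]
    return replace(MNParameters(g_shab=g_shab), **overrides)


def preset_current(name: str) -> float:
    """Calibrated network operating current (pA) for a named preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name][1]
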