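#!/usr/bin/env python
"""Single-neuron excitability along the Shab-conductance axis.

For each preset (HOM, SNL, SNIC, Hopf): resting potential, rheobase,
minimum sustained onset rate, operational excitability class, and an f-I
curve.  The headline check is the class sequence HOM -> SNIC -> Hopf with
a finite (~47 Hz) onset rate in the high-Shab regime and arbitrarily low
onset rates in the SNIC regime.

Writes results/excitability.csv and results/f_i_curves.csv.
"""

from pathlib import Path

import pandas as pd

from splaycpg.neuron import (classify_excitability, f_I_curve, onset_rate,
                             resting_state, rheobase)
from splaycpg.presets import PRESETS, preset_params

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows, fi_rows = [], []
for name in ("HOM", "SNL", "SNIC", "Hopf"):
    p = preset_params(name)
    rest = resting_state(p, 0.0).v
    I_rh = rheobase(p, probe_ms=2000.0)
    r_on = onset_rate(p)
    cls = classify_excitability(p)
    rows.append({"preset": name, "g_shab_nS": p.g_shab, "rest_mV": rest,
                 "rheobase_pA": I_rh, "onset_rate_hz": r_on, "class": cls})
    print(f"{name}: g_shab={p.g_shab:.2f} nS rest={rest:.1f} mV "
          f"rheobase={I_rh:.1f} pA onset={r_on:.1f} Hz class={cls}")
    for I, rate in f_I_curve(p, [0.5 * I_rh, 1.02 * I_rh, 1.2 * I_rh,
                                 1.5 * I_rh, 2.0 * I_rh], t_max_ms=5000.0):
        fi_rows.append({"preset": name, "I_pA": I, "rate_Hz": rate})

pd.DataFrame(rows).to_csv(OUT / "excitability.csv", index=False)
pd.DataFrame(fi_rows).to_csv(OUT / "f_i_curves.csv", index=False)
print(f"wrote {OUT}/excitability.csv and {OUT}/f_i_curves.csv")
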