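"""End-to-end experiment recipes over the network simulator and statistics.

Each recipe reproduces one of the study's simulation quantifications:

* ``weak_vs_strong`` — MN4-MN5 synchronization indices of the low-Shab
  (SNL) network under weak homogeneous (CC 0.005) vs strong (3 nS)
  coupling, with a two-sided Mann-Whitney comparison.
* ``snl_vs_snic`` — MN3-MN4 synchronization indices of the weighted
  (heterogeneous) network with SNL- vs SNIC-regime neurons.
* ``cc_sweep`` — mean splayness as a function of the coupling coefficient.
* ``sequence_preference`` — distribution over the six MN1-4 firing orders
  for homogeneous vs heterogeneous coupling.
* ``calcium_ratio`` — sync/splay fluctuation ratio of fibre-averaged
  calcium across firing rates.

Profiles: ``desk`` (10 replicates, 30 s, dt 20 µs) and ``paper``
(10 replicates, 60 s, dt 3 µs).  All randomness derives from a single base
seed; replicate seeds are deterministic functions of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calcium import splay_vs_sync_ratio
from .coupling import g_gap_from_cc
from .neuron import MNParameters, find_limit_cycle
from .network import SimulationConfig, build_coupling, init_random_phases, simulate
from .presets import preset_current, preset_params
from .stats import (SEQUENCE_CLASSES, compare_index_sets, pair_sync_index,
                    sequence_statistics, splayness)

TRANSIENT_S = 3.0

PROFILES = {
    "desk": dict(n_reps=10, duration=30.0, dt=0.02),
    "paper": dict(n_reps=10, duration=60.0, dt=0.003),
}


def _rep_seed(base: int, k: int, salt: int = 0) -> int:
    return (int(base) * 9973 + 7919 * k + salt) % (2**31 - 1)


def _run_reps(params: MNParameters, I_in: float, coupling: np.ndarray,
              seed: int, n_reps: int, duration: float, dt: float,
              sigma: float = 0.949):
    """Seeded replicate simulations; returns trimmed SpikeTrains per rep."""
    cycle = find_limit_cycle(params, I_in)
    out = []
    for k in range(n_reps):
        init = init_random_phases(params, I_in, _rep_seed(seed, k), n=5, cycle=cycle)
        cfg = SimulationConfig(duration=duration, dt=dt, sigma=sigma,
                               seed=_rep_seed(seed, k, salt=1), I_in=I_in)
        res = simulate(params, coupling, cfg, initial_states=init)
        out.append(res.trains.trimmed(TRANSIENT_S))
    return out


def weak_vs_strong(seed: int = 0, profile: str = "desk") -> dict:
    """Fig-3d-style comparison of MN4-MN5 sync under weak vs strong coupling."""
    prof = PROFILES[profile]
    p = preset_params("SNL")
    I = preset_current("SNL")
    rows = []
    groups = {}
    for label, preset in [("weak", "homogeneous"), ("strong", "strong")]:
        reps = _run_reps(p, I, build_coupling(preset), seed, **prof)
        idx = [pair_sync_index(tr[3], tr[4]) for tr in reps]
        groups[label] = idx
        rows += [{"condition": label, "replicate": k, "r_mn4_mn5": v}
                 for k, v in enumerate(idx)]
    U, pval = compare_index_sets(groups["strong"], groups["weak"])
    return {"table": pd.DataFrame(rows),
            "median_weak": float(np.median(groups["weak"])),
            "median_strong": float(np.median(groups["strong"])),
            "U": U, "p": pval}


def snl_vs_snic(seed: int = 0, profile: str = "desk") -> dict:
    """MN3-MN4 sync of the weighted network: SNL vs SNIC excitability."""
    prof = PROFILES[profile]
    G = build_coupling("heterogeneous")
    rows = []
    groups = {}
    for regime in ("SNL", "SNIC"):
        p = preset_params(regime)
        I = preset_current(regime)
        reps = _run_reps(p, I, G, seed, **prof)
        idx = [pair_sync_index(tr[2], tr[3]) for tr in reps]
        groups[regime] = idx
        rows += [{"condition": regime, "replicate": k, "r_mn3_mn4": v}
                 for k, v in enumerate(idx)]
    U, pval = compare_index_sets(groups["SNIC"], groups["SNL"])
    return {"table": pd.DataFrame(rows),
            "median_snl": float(np.median(groups["SNL"])),
            "median_snic": float(np.median(groups["SNIC"])),
            "U": U, "p": pval}


def cc_sweep(seed: int = 0, cc_values=(0.005, 0.05, 0.15, 0.25),
             n_reps: int = 10, duration: float = 23.0, dt: float = 0.02) -> dict:
    """Mean splayness vs coupling coefficient (reduced Fig-3c grid)."""
    p = preset_params("SNL")
    I = preset_current("SNL")
    g_L = p.g_L
    rows = []
    for cc in cc_values:
        g = g_gap_from_cc(cc, g_L)
        G = build_coupling(matrix=np.full((5, 5), g))
        reps = _run_reps(p, I, G, seed, n_reps=n_reps, duration=duration, dt=dt)
        for k, tr in enumerate(reps):
            rows.append({"cc": cc, "g_gap_nS": g, "replicate": k,
                         "splayness": splayness(tr)})
    df = pd.DataFrame(rows)
    means = df.groupby("cc")["splayness"].mean().rename("mean_splayness")
    return {"table": df, "means": means.reset_index()}


def sequence_preference(seed: int = 0, n_reps: int = 5,
                        duration: float = 120.0, dt: float = 0.02) -> dict:
    """Firing-order distributions: homogeneous vs heterogeneous coupling."""
    p = preset_params("SNL")
    I = preset_current("SNL")
    rows = []
    for preset in ("homogeneous", "heterogeneous"):
        reps = _run_reps(p, I, build_coupling(preset), seed,
                         n_reps=n_reps, duration=duration, dt=dt)
        pooled = {c: 0 for c in SEQUENCE_CLASSES}
        irregular = 0
        for tr in reps:
            st = sequence_statistics(tr)
            for c in SEQUENCE_CLASSES:
                pooled[c] += st["counts"][c]
            irregular += st["n_irregular"]
        n_ok = sum(pooled.values())
        for c in SEQUENCE_CLASSES:
            rows.append({"coupling": preset, "sequence": c,
                         "count": pooled[c],
                         "probability": pooled[c] / n_ok if n_ok else np.nan})
    return {"table": pd.DataFrame(rows)}


def calcium_ratio(rates_hz=(0.5, 2.0, 5.0, 10.0)) -> dict:
    """Sync/splay calcium fluctuation ratio across firing rates."""
    rows = [{"rate_hz": r,
             "ratio_sd": splay_vs_sync_ratio(r, metric="sd"),
             "ratio_p2t": splay_vs_sync_ratio(r, metric="p2t")}
            for r in rates_hz]
    return {"table": pd.DataFrame(rows)}


RECIPES = {
    "weak_vs_strong": weak_vs_strong,
    "snl_vs_snic": snl_vs_snic,
    "cc_sweep": cc_sweep,
    "sequence_preference": sequence_preference,
    "calcium_ratio": calcium_ratio,
}


def run_recipe(name: str, seed: int = 0, **kw) -> dict:
    if name not in RECIPES:
        raise KeyError(f"unknown recipe {name!r}; choose from {sorted(RECIPES)}")
    fn = RECIPES[name]
    if name == "calcium_ratio":
        return fn(**kw)
    return fn(seed=seed, **kw)
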