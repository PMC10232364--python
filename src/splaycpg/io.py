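"""CSV / JSON / YAML I/O for spike trains, configurations and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trains import SpikeTrains


def write_trains_csv(trains: SpikeTrains, path) -> None:
    """Write spike trains as CSV with columns (neuron_id, t_s); 1-based ids."""
    rows = [(i + 1, t) for i, ts in enumerate(trains.times) for t in ts]
    pd.DataFrame(rows, columns=["neuron_id", "t_s"]).to_csv(path, index=False)


def read_trains_csv(path, breaks_path=None) -> SpikeTrains:
    """Read spike trains from a (neuron_id, t_s) CSV; optional breaks file
    with (start_s, end_s) rows."""
    df = pd.read_csv(path)
    ids = sorted(df["neuron_id"].unique())
    times = [np.sort(df.loc[df["neuron_id"] == i, "t_s"].to_numpy()) for i in ids]
    breaks = []
    if breaks_path is not None:
        bdf = pd.read_csv(breaks_path)
        breaks = list(zip(bdf["start_s"], bdf["end_s"]))
    lo = min((t[0] for t in times if len(t)), default=0.0)
    hi = max((t[-1] for t in times if len(t)), default=0.0)
    return SpikeTrains(times, span=(lo, hi), breaks=breaks)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2) + "\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
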