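"""Spike-train container shared by the simulator, generator and statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpikeTrains:
    """Per-neuron spike times in seconds, strictly increasing.

    ``span`` is the recorded interval; ``breaks`` is a list of (start, end)
    intervals (in s) during which the recording is interrupted (e.g. flight
    bout pauses); spike times never fall inside a break.
    """

    times: list
    span: tuple = (0.0, 0.0)
    breaks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        for i, t in enumerate(self.times):
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"spike times of neuron {i} must be strictly increasing")
        for s, e in self.breaks:
            if e <= s:
                raise ValueError("break intervals must have positive length")

    @property
    def n_neurons(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.times[i]

    def subset(self, idx) -> "SpikeTrains":
        return SpikeTrains([self.times[i] for i in idx], span=self.span,
                           breaks=list(self.breaks))

    def shifted(self, dt_s: float) -> "SpikeTrains":
        return SpikeTrains([t + dt_s for t in self.times],
                           span=(self.span[0] + dt_s, self.span[1] + dt_s),
                           breaks=[(s + dt_s, e + dt_s) for s, e in self.breaks])

    def trimmed(self, t_start: float, t_end: float | None = None) -> "SpikeTrains":
        """Keep only spikes in [t_start, t_end]."""
        t_end = self.span[1] if t_end is None else t_end
        return SpikeTrains([t[(t >= t_start) & (t <= t_end)] for t in self.times],
                           span=(t_start, t_end), breaks=list(self.breaks))
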