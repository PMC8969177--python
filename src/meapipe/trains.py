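"""Spike-train container shared by the generator, detector and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpikeTrain:
    """Ordered spike times (seconds from recording start) for one electrode.

    Times are 0-based seconds; the analysis interval is the half-open
    ``[0, duration_s)``.  ``amplitudes_v`` optionally carries the per-spike
    peak amplitude in volts (filled in by detection, absent for synthetic
    ground truth).
    """

    times_s: np.ndarray
    duration_s: float
    electrode: str = ""
    well: str = ""
    amplitudes_v: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.times_s.ndim != 1:
            raise ValueError("times_s must be one-dimensional")
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            raise ValueError("spike times must be sorted")
        if self.times_s.size and (
            self.times_s[0] < 0 or self.times_s[-1] > self.duration_s
        ):
            raise ValueError("spike times must lie within [0, duration_s]")

    def __len__(self) -> int:
        return int(self.times_s.size)

    @property
    def n_spikes(self) -> int:
        return len(self)

    def firing_rate_hz(self) -> float:
        """Mean firing rate over the whole recording, in Hz."""
        return len(self) / self.duration_s

    def isis(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.times_s)

    def shifted(self, offset_s: float, duration_s: float | None = None) -> "SpikeTrain":
        """Translate all spike times by ``offset_s`` (new duration optional)."""
        return SpikeTrain(
            self.times_s + offset_s,
            duration_s if duration_s is not None else self.duration_s,
            electrode=self.electrode,
            well=self.well,
            amplitudes_v=self.amplitudes_v,
        )
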