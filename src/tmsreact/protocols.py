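"""Stimulation protocol schedulers for iTBS and 10-Hz rTMS.

Both protocols stimulate bilateral M1 (two sides). The iTBS train is the
standard 600-pulse-per-side structure: triplet bursts at 50 Hz repeated at
5 Hz for 2 s (10 bursts = 30 pulses per train), 20 trains per side with
8-s inter-train intervals. The 10-Hz protocol delivers 20 trains of 30
pulses at 10 Hz per side with 40-s intervals. Total pulse counts are
always derived from the train structure, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class StimProtocol:
    kind: str                      # "iTBS" or "rTMS10"
    sides: int
    trains_per_side: int
    pulses_per_train: int
    intra_train_rate: float        # Hz; pulse rate within a burst (iTBS) or train (rTMS)
    inter_train_interval: float    # s, gap between train onsets' ends
    pulses_per_burst: int = 1      # >1 only for burst protocols
    burst_rate: float | None = None  # Hz between burst onsets (iTBS: 5)

    def __post_init__(self) -> None:
        for name in ("sides", "trains_per_side", "pulses_per_train", "pulses_per_burst"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")

    @property
    def total_pulses(self) -> int:
        return self.sides * self.trains_per_side * self.pulses_per_train

    def train_pulse_times(self) -> np.ndarray:
        """Pulse onset times (s) within a single train, t=0 at train start."""
        if self.pulses_per_burst > 1:
            assert self.burst_rate is not None
            n_bursts = self.pulses_per_train // self.pulses_per_burst
            burst_onsets = np.arange(n_bursts) / self.burst_rate
            within = np.arange(self.pulses_per_burst) / self.intra_train_rate
            return (burst_onsets[:, None] + within[None, :]).ravel()
        return np.arange(self.pulses_per_train) / self.intra_train_rate

    def side_pulse_times(self) -> np.ndarray:
        """Pulse times (s) for one side's full session."""
        train = self.train_pulse_times()
        train_span = train[-1] + 1.0 / self.intra_train_rate
        onsets = np.arange(self.trains_per_side) * (train_span + self.inter_train_interval)
        return (onsets[:, None] + train[None, :]).ravel()

    @property
    def duration_per_side(self) -> float:
        """Session length per side in seconds (last pulse time)."""
        return float(self.side_pulse_times()[-1])


def build_protocol(kind: str) -> StimProtocol:
    """Protocol for ``kind`` in {"iTBS", "rTMS10"}."""
    if kind == "iTBS":
        return StimProtocol(
            kind="iTBS", sides=2, trains_per_side=20, pulses_per_train=30,
            intra_train_rate=50.0, inter_train_interval=8.0,
            pulses_per_burst=3, burst_rate=5.0,
        )
    if kind == "rTMS10":
        return StimProtocol(
            kind="rTMS10", sides=2, trains_per_side=20, pulses_per_train=30,
            intra_train_rate=10.0, inter_train_interval=40.0,
        )
    raise ValueError(f"unknown protocol kind {kind!r}; expected 'iTBS' or 'rTMS10'")
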