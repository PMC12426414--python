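"""In-memory containers shared across the pipeline stages.

Units are microvolts throughout; time axes are milliseconds relative to the
TMS pulse (t = 0 at pulse onset) for epoched data, and seconds from record
start for continuous data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage


@dataclass
class RestingRecording:
    """Continuous multichannel EEG: channels x samples, in microvolts."""

    data: np.ndarray
    fs: float
    montage: Montage
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TepEpochs:
    """TMS-locked epochs: trials x channels x time, in microvolts.

    ``times`` is the epoch time axis in milliseconds; it must contain 0
    (the pulse sample). ``stim_side`` is the stimulated hemisphere,
    ``stim_role`` the M1(+)/M1(-) role derived from the more affected limb.
    """

    data: np.ndarray
    times: np.ndarray
    montage: Montage
    fs: float = 1000.0
    stim_side: str | None = None
    stim_role: str | None = None
    interpolated_window: tuple[float, float] | None = None
    rejected_trials: list[int] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length mismatch")
        if not np.isclose(self.times, 0.0).any():
            raise ValueError("epoch time axis must include t = 0 (the pulse)")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_index(self, t_ms: float) -> int:
        """Index of the sample closest to ``t_ms`` milliseconds."""
        return int(np.argmin(np.abs(self.times - t_ms)))
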