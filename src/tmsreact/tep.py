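"""TMS-evoked-potential processing.

Stages: epoch a continuous record around pulse events (-1000..1000 ms),
cubic-interpolate the pulse-artifact window (-5..15 ms), reject trials
with residual large excursions, average with pre-pulse baseline
correction, and quantify the evoked response as

* GMFA(t) — global mean field amplitude, the population standard
  deviation of the channel voltages at each time point,
      GMFA(t) = sqrt( sum_i (V_i(t) - V_mean(t))^2 / K ),
* local TEP — unweighted mean over the nine electrodes surrounding the
  stimulated M1,
* component peaks — P30, N45, P60, N100, P180 as sign-appropriate local
  extrema within literature-standard search windows (all components are
  maxima on the non-negative GMFA trace).

M1(+) denotes the hemisphere contralateral to the more affected upper
limb, M1(-) the ipsilateral one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d

from .containers import RestingRecording, TepEpochs
from .montage import Montage

#: default component search windows (ms), configurable at call sites
DEFAULT_PEAK_WINDOWS = {
    "P30": (20.0, 40.0),
    "N45": (40.0, 55.0),
    "P60": (55.0, 80.0),
    "N100": (85.0, 140.0),
    "P180": (150.0, 250.0),
}


@dataclass
class EvokedTrace:
    """A single evoked time course (GMFA, local-cluster or channel mean)."""

    kind: str                    # "gmfa" | "local" | "channel"
    times: np.ndarray            # ms
    values: np.ndarray           # uV
    n_trials: int
    baseline: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class Peak:
    name: str
    window: tuple[float, float]
    found: bool
    latency_ms: float | None = None
    amplitude_uv: float | None = None


PeakTable = dict[str, Peak]


def epoch(
    raw: RestingRecording,
    events_s: np.ndarray,
    window_ms: tuple[float, float] = (-1000.0, 1000.0),
    stim_side: str | None = None,
    stim_role: str | None = None,
) -> TepEpochs:
    """Cut one epoch per pulse event from a continuous record.

    ``events_s`` are pulse times in seconds from record start; the sample
    at t=0 of each epoch is the sample at the pulse time. Events whose
    window extends beyond the record are dropped with a warning.
    """
    lo_ms, hi_ms = window_ms
    lo = int(round(lo_ms * raw.fs / 1000.0))
    hi = int(round(hi_ms * raw.fs / 1000.0))
    times = np.arange(lo, hi + 1) * 1000.0 / raw.fs
    kept, dropped = [], 0
    for ev in np.asarray(events_s, float):
        center = int(round(ev * raw.fs))
        if center + lo < 0 or center + hi >= raw.n_samples:
            dropped += 1
            continue
        kept.append(raw.data[:, center + lo: center + hi + 1])
    if dropped:
        warnings.warn(f"dropped {dropped} event(s) without full epoch support",
                      stacklevel=2)
    if not kept:
        raise ValueError("no events with full window support")
    return TepEpochs(
        data=np.stack(kept), times=times, montage=raw.montage, fs=raw.fs,
        stim_side=stim_side, stim_role=stim_role,
        meta={"n_events_dropped": dropped},
    )


def interpolate_artifact(
    epochs: TepEpochs,
    window_ms: tuple[float, float] = (-5.0, 15.0),
    n_anchor: int = 5,
) -> TepEpochs:
    """Replace samples strictly inside ``window_ms`` by cubic interpolation.

    The interpolant is anchored on ``n_anchor`` samples on each side of the
    window; all samples at or outside the window edges are bit-identical
    to the input.
    """
    t = epochs.times
    lo, hi = window_ms
    if lo <= t[0] or hi >= t[-1]:
        raise ValueError(f"window {window_ms} must lie strictly inside the "
                         f"epoch span ({t[0]}, {t[-1]})")
    inside = (t > lo) & (t < hi)
    if not inside.any():
        return epochs
    first, last = np.flatnonzero(inside)[[0, -1]]
    left = np.arange(first - n_anchor, first)
    right = np.arange(last + 1, last + 1 + n_anchor)
    if left[0] < 0 or right[-1] >= t.size:
        raise ValueError("not enough samples around the window to anchor "
                         "the interpolant")
    anchors = np.concatenate([left, right])
    data = epochs.data.copy()
    f = interp1d(t[anchors], data[:, :, anchors], kind="cubic", axis=-1)
    data[:, :, inside] = f(t[inside])
    return TepEpochs(
        data=data, times=t, montage=epochs.montage, fs=epochs.fs,
        stim_side=epochs.stim_side, stim_role=epochs.stim_role,
        interpolated_window=(lo, hi),
        rejected_trials=list(epochs.rejected_trials), meta=dict(epochs.meta),
    )


def reject_epochs(
    epochs: TepEpochs,
    abs_threshold_uv: float = 100.0,
    exclude_window_ms: tuple[float, float] | None = None,
) -> TepEpochs:
    """Drop trials exceeding ``abs_threshold_uv`` on any channel.

    Samples inside ``exclude_window_ms`` (default: the interpolated
    window, if any) are ignored when thresholding, so residual pulse
    artifacts do not drive rejection.
    """
    if abs_threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    if exclude_window_ms is None:
        exclude_window_ms = epochs.interpolated_window
    consider = np.ones(epochs.times.size, dtype=bool)
    if exclude_window_ms is not None:
        lo, hi = exclude_window_ms
        consider &= ~((epochs.times >= lo) & (epochs.times <= hi))
    peak = np.max(np.abs(epochs.data[:, :, consider]), axis=(1, 2))
    bad = np.flatnonzero(peak > abs_threshold_uv)
    if bad.size == epochs.n_trials:
        raise RuntimeError(
            f"all {epochs.n_trials} trials exceed the {abs_threshold_uv} uV "
            f"rejection threshold")
    keep = np.setdiff1d(np.arange(epochs.n_trials), bad)
    return TepEpochs(
        data=epochs.data[keep], times=epochs.times, montage=epochs.montage,
        fs=epochs.fs, stim_side=epochs.stim_side, stim_role=epochs.stim_role,
        interpolated_window=epochs.interpolated_window,
        rejected_trials=sorted(set(epochs.rejected_trials) | set(bad.tolist())),
        meta=dict(epochs.meta),
    )


def average_tep(
    epochs: TepEpochs, baseline_ms: tuple[float, float] | None = (-500.0, -50.0)
) -> np.ndarray:
    """Trial-average evoked matrix (channels x time), baseline-corrected.

    The per-channel mean over ``baseline_ms`` is subtracted; pass None to
    skip baseline correction.
    """
    evoked = epochs.data.mean(axis=0)
    if baseline_ms is not None:
        lo, hi = baseline_ms
        sel = (epochs.times >= lo) & (epochs.times <= hi)
        if not sel.any():
            raise ValueError(f"baseline window {baseline_ms} has no samples")
        evoked = evoked - evoked[:, sel].mean(axis=1, keepdims=True)
    return evoked


def gmfa(evoked: np.ndarray, times: np.ndarray, n_trials: int = 0) -> EvokedTrace:
    """Global mean field amplitude: across-channel population SD per sample."""
    evoked = np.atleast_2d(np.asarray(evoked, float))
    if evoked.shape[0] < 2:
        raise ValueError("GMFA needs at least two channels")
    values = evoked.std(axis=0, ddof=0)
    return EvokedTrace(kind="gmfa", times=np.asarray(times, float),
                       values=values, n_trials=n_trials)


def local_tep(
    evoked: np.ndarray, times: np.ndarray, montage: Montage, cluster: str,
    n_trials: int = 0,
) -> EvokedTrace:
    """Unweighted mean over a montage cluster (e.g. the nine M1 electrodes)."""
    idx = montage.cluster_indices(cluster)
    values = np.asarray(evoked, float)[idx].mean(axis=0)
    return EvokedTrace(kind="local", times=np.asarray(times, float),
                       values=values, n_trials=n_trials,
                       meta={"cluster": cluster})


def _local_extrema(y: np.ndarray, maxima: bool) -> np.ndarray:
    """Indices of strict-or-plateau interior local extrema."""
    s = y if maxima else -y
    idx = []
    for i in range(1, len(s) - 1):
        if s[i] >= s[i - 1] and s[i] >= s[i + 1] and (s[i] > s[i - 1] or s[i] > s[i + 1]):
            idx.append(i)
    return np.asarray(idx, dtype=int)


def extract_peaks(
    trace: EvokedTrace,
    windows: dict[str, tuple[float, float]] | None = None,
) -> PeakTable:
    """Locate evoked components as in-window local extrema.

    P-components are local maxima and N-components local minima on
    channel/local traces; on a GMFA trace every component is a maximum
    (the trace is non-negative). The largest-magnitude extremum wins;
    equal extrema tie-break to the earliest latency. ``found`` is False
    when no interior extremum of the right polarity lies in the window.
    """
    windows = windows or DEFAULT_PEAK_WINDOWS
    t, y = trace.times, trace.values
    table: PeakTable = {}
    for name, (lo, hi) in windows.items():
        if lo < t[0] or hi > t[-1]:
            raise ValueError(f"search window {name} {lo, hi} outside trace span")
        maxima = trace.kind == "gmfa" or name.startswith("P")
        sel = np.flatnonzero((t >= lo) & (t <= hi))
        ext = _local_extrema(y[sel[0] - 1: sel[-1] + 2], maxima)
        ext = ext + sel[0] - 1
        ext = ext[(t[ext] >= lo) & (t[ext] <= hi)] if ext.size else ext
        if ext.size == 0:
            table[name] = Peak(name=name, window=(lo, hi), found=False)
            continue
        amps = y[ext]
        best = amps.max() if maxima else amps.min()
        # earliest among ties at the winning amplitude
        pick = ext[np.flatnonzero(amps == best)[0]]
        table[name] = Peak(name=name, window=(lo, hi), found=True,
                           latency_ms=float(t[pick]),
                           amplitude_uv=float(y[pick]))
    return table


def map_m1_sides(affected_upper_limb: str) -> dict[str, str]:
    """M1(+) is contralateral to the more affected upper limb."""
    if affected_upper_limb not in ("left", "right"):
        raise ValueError(f"unknown side {affected_upper_limb!r}")
    other = "left" if affected_upper_limb == "right" else "right"
    return {"M1plus": other, "M1minus": affected_upper_limb}
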