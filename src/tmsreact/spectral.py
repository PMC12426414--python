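"""Resting-state spectral analysis: Welch PSD, relative band power, slowing ratio.

The band partition follows the clinical-EEG convention delta (1-4 Hz) with
sub-bands delta1 (1-2) / delta2 (2-4), theta (4-8), alpha (8-13), beta
(13-32) and gamma (32-45). The slowing index is

    ratio1 = (delta + theta) / (alpha + beta)

computed from absolute band powers (the total-power denominator cancels, so
relative powers give the same number).

Band powers are Riemann sums of the one-sided PSD over half-open frequency
bins ``low <= f < high``, so adjacent bands share no bin and the relative
powers over the partition sum to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import RestingRecording
from .montage import Montage


def _default_bands() -> dict[str, tuple[float, float]]:
    return {
        "delta": (1.0, 4.0),
        "delta1": (1.0, 2.0),
        "delta2": (2.0, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 13.0),
        "beta": (13.0, 32.0),
        "gamma": (32.0, 45.0),
    }


@dataclass(frozen=True)
class BandSet:
    """Ordered map of band name -> (low Hz, high Hz)."""

    bands: dict[str, tuple[float, float]] = field(default_factory=_default_bands)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: low must be < high, got ({lo}, {hi})")
        b = self.bands
        if "delta" in b and "delta1" in b and "delta2" in b:
            if not (b["delta1"][0] == b["delta"][0]
                    and b["delta1"][1] == b["delta2"][0]
                    and b["delta2"][1] == b["delta"][1]):
                raise ValueError("delta1 and delta2 must partition delta exactly")

    #: names forming the disjoint 1-45 Hz partition (excludes the sub-bands)
    @property
    def partition(self) -> list[str]:
        return [n for n in self.bands if n not in ("delta1", "delta2")]

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]

    def __iter__(self):
        return iter(self.bands)


@dataclass
class SpectralSummary:
    """Per-channel PSD, band powers (uV^2), relative powers and ratio1."""

    freqs: np.ndarray
    psd: np.ndarray  # channels x freqs, uV^2/Hz
    abs_power: dict[str, np.ndarray]
    rel_power: dict[str, np.ndarray]
    ratio1: np.ndarray
    bands: BandSet
    total_range: tuple[float, float]


def welch_psd(
    rec: RestingRecording,
    segment_seconds: float = 2.0,
    overlap_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD per channel (Hann window, constant detrend).

    With 2-s segments at 1000 Hz the grid step is 0.5 Hz. The density is
    normalised so that its integral over frequency approximates the signal
    variance.

    Returns
    -------
    freqs, psd
        Frequency grid (Hz) and channels x freqs density (uV^2/Hz).
    """
    nperseg = int(round(segment_seconds * rec.fs))
    if rec.n_samples < 2 * nperseg:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than two "
            f"{nperseg}-sample segments"
        )
    noverlap = int(round(overlap_fraction * nperseg))
    freqs, psd = signal.welch(
        rec.data, fs=rec.fs, window="hann", nperseg=nperseg,
        noverlap=noverlap, detrend="constant", scaling="density", axis=-1,
    )
    return freqs, psd


def integrate_psd(
    freqs: np.ndarray, psd: np.ndarray, low: float, high: float,
    closed: bool = True,
) -> np.ndarray:
    """Band power as a bin sum of PSD * df over ``[low, high]``.

    ``closed=False`` uses the half-open convention ``low <= f < high`` used
    for the band partition; ``closed=True`` includes both endpoints (the
    natural choice for a free-standing integral such as a sinusoid-power
    check).
    """
    df = float(freqs[1] - freqs[0])
    if closed:
        mask = (freqs >= low) & (freqs <= high)
    else:
        mask = (freqs >= low) & (freqs < high)
    return np.sum(psd[..., mask], axis=-1) * df


def relative_band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: BandSet | None = None,
    total_range: tuple[float, float] = (1.0, 45.0),
) -> SpectralSummary:
    """Absolute and relative band power per channel, plus ratio1.

    Relative power is the band power divided by total power over
    ``total_range`` (half-open, matching the union of the partition bands),
    so the partition relative powers sum to 1.
    """
    bands = bands or BandSet()
    psd = np.atleast_2d(psd)
    if freqs[0] > total_range[0] or freqs[-1] < total_range[1]:
        raise ValueError(
            f"frequency grid [{freqs[0]}, {freqs[-1]}] does not cover "
            f"total_range {total_range}"
        )
    total = integrate_psd(freqs, psd, *total_range, closed=False)
    if np.any(total <= 0):
        raise ZeroDivisionError("total power is zero on at least one channel")
    abs_power = {
        name: integrate_psd(freqs, psd, lo, hi, closed=False)
        for name, (lo, hi) in bands.bands.items()
    }
    rel_power = {name: p / total for name, p in abs_power.items()}
    ratio1 = slow_fast_ratio(abs_power)
    return SpectralSummary(
        freqs=freqs, psd=psd, abs_power=abs_power, rel_power=rel_power,
        ratio1=ratio1, bands=bands, total_range=total_range,
    )


def slow_fast_ratio(abs_power: dict[str, np.ndarray]) -> np.ndarray:
    """Slowing index (delta + theta) / (alpha + beta) per channel."""
    num = np.asarray(abs_power["delta"]) + np.asarray(abs_power["theta"])
    den = np.asarray(abs_power["alpha"]) + np.asarray(abs_power["beta"])
    if np.any(den <= 0):
        raise ZeroDivisionError("alpha + beta power is zero: ratio1 undefined")
    return num / den


def region_average(
    values: np.ndarray, montage: Montage, cluster: str
) -> float:
    """Unweighted mean of a per-channel metric over a montage cluster."""
    idx = montage.cluster_indices(cluster)
    return float(np.mean(np.asarray(values)[idx]))


def spectral_summary(
    rec: RestingRecording,
    bands: BandSet | None = None,
    segment_seconds: float = 2.0,
    overlap_fraction: float = 0.5,
    total_range: tuple[float, float] = (1.0, 45.0),
) -> SpectralSummary:
    """Convenience wrapper: Welch PSD then band powers in one call."""
    freqs, psd = welch_psd(rec, segment_seconds, overlap_fraction)
    return relative_band_power(freqs, psd, bands, total_range)
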