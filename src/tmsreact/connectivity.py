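"""Phase-lag-index (PLI) functional connectivity between EEG channels.

PLI measures the asymmetry of the instantaneous phase-difference
distribution between two channels:

    PLI(a, b) = | < sign( sin( phi_a(t) - phi_b(t) ) ) >_t |

It is 1 for a constant nonzero lag, and 0 both for independent phases and
for zero-lag (volume-conduction) coupling, because sign(sin 0) = 0.

Phases come from a zero-phase FIR band-pass followed by the analytic
signal; samples within one filter length of either record edge are masked
out. The masked record is split into 2-s epochs matching the spectral
segmentation; the signed mean of sign(sin(dphi)) is computed per epoch,
averaged across epochs, and the absolute value is taken last, which equals
the whole-record estimate while keeping per-epoch bookkeeping and avoiding
the small-sample bias a per-epoch absolute value would introduce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import RestingRecording
from .montage import Montage


@dataclass
class PhaseSet:
    """Instantaneous phase per channel for one frequency band."""

    band: tuple[float, float]
    phases: np.ndarray      # channels x samples, wrapped to (-pi, pi]
    mask: np.ndarray        # boolean, samples free of filter edge transients
    fs: float
    montage: Montage


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel PLI matrix for one band."""

    band: tuple[float, float]
    matrix: np.ndarray
    montage: Montage

    def pair(self, label_a: str, label_b: str) -> float:
        """PLI for a channel pair; order-invariant, 0 on the diagonal."""
        i = self.montage.index(label_a)
        j = self.montage.index(label_b)
        return float(self.matrix[i, j])


def design_bandpass(band: tuple[float, float], fs: float, min_cycles: float = 3.0) -> np.ndarray:
    """Hamming-windowed FIR band-pass, order >= min_cycles of the low edge.

    Transition width is 25% of each band edge; taps are odd so the filter
    has integer group delay (irrelevant after filtfilt, but keeps the edge
    mask exact).
    """
    low, high = band
    nyq = fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"invalid band {band}")
    if high >= nyq:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {nyq}")
    numtaps = int(np.ceil(min_cycles * fs / low))
    if numtaps % 2 == 0:
        numtaps += 1
    taps = signal.firwin(
        numtaps, [low, high], pass_zero=False, window="hamming", fs=fs
    )
    return taps


def band_phase(rec: RestingRecording, band: tuple[float, float]) -> PhaseSet:
    """Zero-phase band-pass then analytic-signal phase per channel."""
    taps = design_bandpass(band, rec.fs)
    if rec.n_samples <= 3 * len(taps):
        raise ValueError(
            f"recording too short ({rec.n_samples} samples) for the "
            f"{len(taps)}-tap band-pass"
        )
    filtered = signal.filtfilt(taps, [1.0], rec.data, axis=-1)
    phases = np.angle(signal.hilbert(filtered, axis=-1))
    mask = np.zeros(rec.n_samples, dtype=bool)
    mask[len(taps):rec.n_samples - len(taps)] = True
    return PhaseSet(band=band, phases=phases, mask=mask, fs=rec.fs,
                    montage=rec.montage)


def pli_matrix(phases: PhaseSet, epoch_seconds: float = 2.0) -> ConnectivityMatrix:
    """PLI between all channel pairs from masked instantaneous phases."""
    valid = phases.phases[:, phases.mask]
    n_ch, n_valid = valid.shape
    if n_ch < 2:
        raise ValueError("PLI needs at least two channels")
    if n_valid < 2 * phases.fs:
        raise ValueError("fewer than 2 s of valid samples after edge masking")
    epoch_len = int(round(epoch_seconds * phases.fs))
    n_epochs = n_valid // epoch_len
    valid = valid[:, : n_epochs * epoch_len].reshape(n_ch, n_epochs, epoch_len)

    mat = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        # signed epoch means, |.| taken after averaging across epochs
        diff = valid[i, None, :, :] - valid[i + 1:, :, :]
        signed = np.mean(np.sign(np.sin(diff)), axis=-1)  # pairs x epochs
        pli = np.abs(np.mean(signed, axis=-1))
        mat[i, i + 1:] = pli
        mat[i + 1:, i] = pli
    return ConnectivityMatrix(band=phases.band, matrix=mat, montage=phases.montage)


def band_pli(
    rec: RestingRecording, band: tuple[float, float], epoch_seconds: float = 2.0
) -> ConnectivityMatrix:
    """Convenience wrapper: band-pass phases then the full PLI matrix."""
    return pli_matrix(band_phase(rec, band), epoch_seconds)


def pair_pli(matrix: ConnectivityMatrix, label_a: str, label_b: str) -> float:
    return matrix.pair(label_a, label_b)
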