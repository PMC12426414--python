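"""Synthetic EEG, TEP and cohort generators with known ground truth.

Every downstream stage of the pipeline is testable against these
generators without any recorded data:

* resting EEG — per-channel sums of band-limited filtered-noise
  oscillations whose variances are controlled exactly, over an optional
  1/f (pink) background, with optional channel pairs sharing a
  band-limited component at a constant phase lag;
* TEP epochs — Gaussian-bump evoked components with configurable latency,
  amplitude, width and topography, plus a pulse-artifact window and white
  trial noise;
* cohorts — two treatment groups with a planted responder structure:
  responders draw lower frontal delta relative power and lower F2-F7
  delta PLI, and larger UPDRS-III improvements.

All generators are pure functions of (spec, seed): the same spec and seed
reproduce bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import RestingRecording, TepEpochs
from .montage import Montage
from .responder import SubjectRecord
from .spectral import BandSet


# ---------------------------------------------------------------------------
# resting EEG


@dataclass(frozen=True)
class RestingSimSpec:
    """Recipe for a synthetic resting recording.

    ``band_fractions`` maps band name (from ``bands``) to the fraction of
    ``total_power`` carried by that band's oscillation; the residual
    1 - sum(fractions) goes to the 1/f background. ``coupled_pairs`` are
    (channel_a, channel_b, band_name, phase_lag_rad) tuples: both channels
    share one band-limited component, channel_b delayed by the given
    constant phase lag at all frequencies in the band.
    """

    duration: float = 420.0           # s; the study records 7-min rest
    fs: float = 1000.0
    band_fractions: dict[str, float] = field(default_factory=dict)
    pink_exponent: float = 1.0
    coupled_pairs: tuple[tuple[str, str, str, float], ...] = ()
    noise_sd: float = 0.0             # uV, white sensor noise
    total_power: float = 100.0        # uV^2 variance of the oscillatory signal
    bands: BandSet = field(default_factory=BandSet)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 4.0:
            raise ValueError("duration must be at least 4 s")
        total = sum(self.band_fractions.values())
        if any(v < 0 for v in self.band_fractions.values()) or total > 1 + 1e-12:
            raise ValueError(
                f"band fractions must be non-negative and sum <= 1 (sum={total:g})")
        highest = max((self.bands[b][1] for b in self.band_fractions), default=0.0)
        for _, _, b, _ in self.coupled_pairs:
            highest = max(highest, self.bands[b][1])
        if self.fs <= 2 * highest:
            raise ValueError(f"fs={self.fs} must exceed twice the highest band "
                             f"edge {highest}")


def _band_noise(rng: np.random.Generator, band: tuple[float, float],
                fs: float, n: int) -> np.ndarray:
    """Unit-variance noise confined exactly to ``[low, high)``.

    White noise is band-limited by zeroing Fourier coefficients outside the
    band (a zero-phase brick-wall), then rescaled to unit empirical
    variance. Spectral masking rather than an FIR filter keeps the band
    confinement and power bookkeeping exact.
    """
    low, high = band
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    # raised-cosine roll-off inside the band edges: keeps all power strictly
    # in [low, high) while avoiding the sharp edge that would smear across
    # bins of a short-window spectral estimate
    taper = min(0.5, 0.25 * (high - low))
    gain = np.zeros_like(freqs)
    core = (freqs >= low + taper) & (freqs < high - taper)
    gain[core] = 1.0
    lo_edge = (freqs >= low) & (freqs < low + taper)
    gain[lo_edge] = 0.5 * (1 - np.cos(np.pi * (freqs[lo_edge] - low) / taper))
    hi_edge = (freqs >= high - taper) & (freqs < high)
    gain[hi_edge] = 0.5 * (1 - np.cos(np.pi * (high - freqs[hi_edge]) / taper))
    y = np.fft.irfft(spec * gain, n=n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _phase_rotate(x: np.ndarray, lag: float) -> np.ndarray:
    """Delay a band-limited signal by a constant phase ``lag`` (radians)."""
    return np.real(signal.hilbert(x) * np.exp(-1j * lag))


def _pink_noise(rng, n: int, exponent: float, fs: float,
                frange: tuple[float, float] = (1.0, 45.0)) -> np.ndarray:
    """Unit-variance 1/f^exponent noise band-limited to ``frange``."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    shape = np.zeros_like(freqs)
    inband = (freqs >= frange[0]) & (freqs <= frange[1])
    shape[inband] = freqs[inband] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_resting_eeg(spec: RestingSimSpec, montage: Montage | None = None
                         ) -> RestingRecording:
    """Generate a resting recording per ``spec`` on ``montage``.

    Each channel receives independent band oscillations with variance
    ``fraction * total_power``, a pink background carrying the residual
    variance, and white noise of ``noise_sd``. Channels named in
    ``coupled_pairs`` share the band component (channel_b phase-delayed),
    giving a PLI near 1 in that band at high SNR.
    """
    montage = montage or Montage()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    n_ch = montage.n_channels

    for a, b, band, _ in spec.coupled_pairs:
        montage.index(a), montage.index(b)
        if band not in spec.bands.bands:
            raise KeyError(f"coupled pair band {band!r} not in band set")

    coupled_by_channel: dict[int, list[tuple[str, np.ndarray]]] = {}
    for a, b, band_name, lag in spec.coupled_pairs:
        shared = _band_noise(rng, spec.bands[band_name], spec.fs, n)
        ia, ib = montage.index(a), montage.index(b)
        coupled_by_channel.setdefault(ia, []).append((band_name, shared))
        coupled_by_channel.setdefault(ib, []).append(
            (band_name, _phase_rotate(shared, lag)))

    residual = max(0.0, 1.0 - sum(spec.band_fractions.values()))
    data = np.zeros((n_ch, n))
    truth_var = {b: np.zeros(n_ch) for b in spec.band_fractions}
    for ch in range(n_ch):
        planted = dict(coupled_by_channel.get(ch, ()))
        for band_name, frac in spec.band_fractions.items():
            if frac == 0:
                continue
            comp = planted.pop(band_name, None)
            if comp is None:
                comp = _band_noise(rng, spec.bands[band_name], spec.fs, n)
            var = frac * spec.total_power
            data[ch] += comp * np.sqrt(var)
            truth_var[band_name][ch] = var
        for band_name, comp in planted.items():
            # coupled band not listed in band_fractions: give it 10% power
            data[ch] += comp * np.sqrt(0.1 * spec.total_power)
        if residual > 1e-12:
            data[ch] += (_pink_noise(rng, n, spec.pink_exponent, spec.fs)
                         * np.sqrt(residual * spec.total_power))
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    return RestingRecording(
        data=data, fs=spec.fs, montage=montage,
        meta={"spec": spec, "band_variance_truth": truth_var},
    )


# ---------------------------------------------------------------------------
# TEP epochs


@dataclass(frozen=True)
class TepComponent:
    """One planted evoked component: a Gaussian bump.

    ``width_ms`` is the full width at half maximum; ``topography`` is a
    per-channel weight vector, or None for a uniform weight of 1.
    """

    name: str
    latency_ms: float
    amplitude_uv: float
    width_ms: float = 10.0
    topography: tuple[float, ...] | None = None


@dataclass(frozen=True)
class TepSimSpec:
    n_trials: int = 100
    components: tuple[TepComponent, ...] = ()
    artifact_window: tuple[float, float] = (-5.0, 15.0)
    artifact_amplitude: float = 0.0    # uV
    noise_sd: float = 0.0              # uV per sample per trial
    inter_trial_interval: float = 3.0  # s
    fs: float = 1000.0
    epoch_span: tuple[float, float] = (-1000.0, 1000.0)  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for c in self.components:
            if not 15.0 < c.latency_ms < 400.0:
                raise ValueError(
                    f"component {c.name!r} latency {c.latency_ms} ms outside (15, 400)")


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def simulate_tep_epochs(spec: TepSimSpec, montage: Montage | None = None
                        ) -> TepEpochs:
    """Generate trials x channels x time epochs with planted components.

    The deterministic evoked template (components scaled by topography) is
    identical across trials; white noise of ``noise_sd`` and the artifact
    burst (random polarity per trial, confined to ``artifact_window``) are
    drawn per trial.
    """
    montage = montage or Montage()
    rng = np.random.default_rng(spec.seed)
    t0, t1 = spec.epoch_span
    times = np.arange(t0, t1 + 1e-9, 1000.0 / spec.fs)
    n_t = times.size
    n_ch = montage.n_channels

    template = np.zeros((n_ch, n_t))
    lo, hi = spec.artifact_window
    for comp in spec.components:
        if lo <= comp.latency_ms <= hi:
            warnings.warn(
                f"component {comp.name!r} latency {comp.latency_ms} ms lies "
                f"inside the artifact window {spec.artifact_window}; kept",
                stacklevel=2,
            )
        sigma = comp.width_ms * _FWHM_TO_SIGMA
        bump = comp.amplitude_uv * np.exp(-0.5 * ((times - comp.latency_ms) / sigma) ** 2)
        topo = (np.ones(n_ch) if comp.topography is None
                else np.asarray(comp.topography, float))
        if topo.size != n_ch:
            raise ValueError(
                f"component {comp.name!r} topography has {topo.size} weights "
                f"for {n_ch} channels")
        template += topo[:, None] * bump[None, :]

    data = np.broadcast_to(template, (spec.n_trials, n_ch, n_t)).copy()
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    if spec.artifact_amplitude != 0:
        in_win = (times >= lo) & (times <= hi)
        decay = np.exp(-(times[in_win] - lo) / 5.0)
        polarity = rng.choice([-1.0, 1.0], size=spec.n_trials)
        data[:, :, in_win] += (spec.artifact_amplitude
                               * polarity[:, None, None] * decay[None, None, :])
    return TepEpochs(
        data=data, times=times, montage=montage, fs=spec.fs,
        meta={"spec": spec},
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class CohortSimSpec:
    """Two-group cohort with a planted responder phenotype.

    Feature means/SDs default to the responder-phenotype condition the
    pipeline is designed around: responders carry lower frontal delta
    relative power (0.355 +/- 0.111 vs 0.442 +/- 0.088) and lower F2-F7
    delta PLI at baseline, and draw larger UPDRS-III improvement rates.
    """

    n_per_group: int = 26
    responder_fraction: float = 0.5
    delta_rel_mean: tuple[float, float] = (0.355, 0.442)   # (responder, non-)
    delta_rel_sd: tuple[float, float] = (0.111, 0.088)
    pli_mean: tuple[float, float] = (0.15, 0.25)
    pli_sd: tuple[float, float] = (0.06, 0.06)
    updrs_baseline_mean: float = 21.0
    updrs_baseline_sd: float = 8.0
    improvement_rate_mean: tuple[float, float] = (0.45, 0.05)  # (resp, non-resp)
    improvement_rate_sd: tuple[float, float] = (0.10, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.updrs_baseline_mean < 0:
            raise ValueError("UPDRS baseline mean must be >= 0")


def simulate_cohort(spec: CohortSimSpec) -> list[SubjectRecord]:
    """Draw a two-group cohort of ``2 * n_per_group`` subjects.

    The generator stores its ground-truth responder class in
    ``true_responder``; the rule-derived label (``SubjectRecord.responder``)
    is computed from the drawn UPDRS-III scores and may disagree near the
    rule boundary.
    """
    rng = np.random.default_rng(spec.seed)
    subjects: list[SubjectRecord] = []
    for group in ("iTBS", "rTMS10"):
        for i in range(spec.n_per_group):
            is_resp = bool(rng.random() < spec.responder_fraction)
            k = 0 if is_resp else 1
            t0 = max(5.0, round(rng.normal(spec.updrs_baseline_mean,
                                           spec.updrs_baseline_sd)))
            rate = rng.normal(spec.improvement_rate_mean[k],
                              spec.improvement_rate_sd[k])
            rate = float(np.clip(rate, -0.5, 1.0))
            t10 = max(0.0, round(t0 * (1.0 - rate)))
            # 1-month scores drift slightly back toward baseline
            t1m = max(0.0, round(t10 + rng.normal(0.15 * (t0 - t10), 1.0)))
            delta_rel = float(np.clip(
                rng.normal(spec.delta_rel_mean[k], spec.delta_rel_sd[k]),
                0.01, 0.99))
            pli = float(np.clip(
                rng.normal(spec.pli_mean[k], spec.pli_sd[k]), 0.0, 1.0))
            tremor_t0 = float(np.clip(round(rng.normal(3.0, 1.5)), 0, 8))
            tremor_t10 = float(np.clip(
                round(tremor_t0 * (1.0 - rate) + rng.normal(0, 0.5)), 0, 8))
            subjects.append(SubjectRecord(
                id=f"{group}-{i:03d}",
                group=group,
                affected_side="left" if rng.random() < 0.5 else "right",
                updrs_t0=float(t0), updrs_t10=float(t10), updrs_t1m=float(t1m),
                subscores={"tremor": {"t0": tremor_t0, "t10": tremor_t10}},
                tug_seconds=float(np.clip(rng.normal(11.2, 2.0), 5.0, 40.0)),
                frontal_delta_rel=delta_rel,
                f2f7_delta_pli=pli,
                true_responder=is_resp,
            ))
    return subjects
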