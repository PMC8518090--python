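"""The pulse-repetition-rate score.

A score for one analysis window is computed in three steps:

1. **Spectrogram** — linear magnitude STFT (``spectrogram`` module).
2. **Amplitude signal** — per column ``t``,

       a(t) = alpha * sum_{signal bins} S[f, t] - beta * sum_{noise bins} S[f, t]

   where ``alpha`` and ``beta`` equalize the maximum possible
   contributions of the signal band and the combined noise bands, and
   negative values are clipped to zero:  ``a_net(t) = max(a(t), 0)``.
3. **Periodicity** — Welch power spectral density of ``a_net`` sampled at
   the spectrogram column rate. The score ``P`` is the maximum PSD value
   whose rate bin falls inside the species' pulse-rate search range
   ``[Rl, Rh]``.

Long recordings are cut into fixed non-overlapping analysis windows, one
score per window (the score sequence ``P_ss``). A *continuity filter* — a
forward-looking moving minimum over ``n`` consecutive windows,

    P_mm(i) = min(P_ss(i), ..., P_ss(i + n - 1)),

keeps only detections sustained for ``n`` windows, rejecting short sounds
that share the species' pulse rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .audio_io import AudioClip, resample, segment
from .spectrogram import (
    FrequencyBand,
    Spectrogram,
    band_to_rows,
    compute_spectrogram,
    max_detectable_pulse_rate,
)

__all__ = [
    "SpeciesProfile",
    "AmplitudeSignal",
    "PulseRateSpectrum",
    "ScoreSequence",
    "amplitude_signal",
    "pulse_rate_spectrum",
    "ribbit_score",
    "score_clip",
    "score_sequence",
    "continuity_filter",
    "default_welch_segment",
]


@dataclass(frozen=True)
class SpeciesProfile:
    """All parameters needed to score a recording for one species.

    Parameters
    ----------
    signal_band
        Frequency range holding the species' vocal energy (positive
        contribution to the amplitude signal).
    noise_bands
        Zero or more ranges of undesired sound (subtracted). A noise band
        may overlap the signal band.
    pulse_rate_range
        ``(Rl, Rh)`` search range for the pulse repetition rate, in pulses
        per second.
    analysis_window_s
        Length of the non-overlapping windows each yielding one score.
    continuity_n
        Moving-minimum length in windows; 1 disables the filter.
    window_samples, overlap_samples
        Spectrogram STFT framing.
    sample_rate
        Audio sample rate the profile is defined at; clips at other rates
        are resampled before scoring.
    welch_segment_columns
        Welch segment length in spectrogram columns; ``None`` picks the
        largest power of two allowing >= 2 averaged segments per analysis
        window (see :func:`default_welch_segment`).
    welch_overlap_fraction
        Fractional overlap between Welch segments (default 0.5).
    band_weighting
        ``"bin_count"`` (default): alpha = 1 / #signal bins, beta =
        1 / #noise bins, so the equal-maximum-contribution property holds
        exactly on the discrete sums. ``"hz"``: literal reciprocal Hz
        ranges, with band sums multiplied by the bin width; the two agree
        when band edges align with bin boundaries.
    """

    signal_band: FrequencyBand
    noise_bands: tuple[FrequencyBand, ...]
    pulse_rate_range: tuple[float, float]
    analysis_window_s: float
    continuity_n: int
    window_samples: int
    overlap_samples: int
    sample_rate: float
    welch_segment_columns: int | None = None
    welch_overlap_fraction: float = 0.5
    band_weighting: str = "bin_count"
    stft_window: str = "hann"
    name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "noise_bands", tuple(self.noise_bands))
        rl, rh = self.pulse_rate_range
        ceiling = max_detectable_pulse_rate(
            self.sample_rate, self.window_samples, self.overlap_samples
        )
        if not 0 < rl < rh <= ceiling:
            raise ValueError(
                f"pulse_rate_range ({rl}, {rh}) must satisfy 0 < Rl < Rh <= "
                f"{ceiling} pps (amplitude-signal Nyquist)"
            )
        nyq = self.sample_rate / 2.0
        for band in (self.signal_band, *self.noise_bands):
            if band.high_hz > nyq:
                raise ValueError(f"band {band} exceeds Nyquist {nyq} Hz")
        if self.continuity_n < 1:
            raise ValueError("continuity_n must be >= 1")
        if self.band_weighting not in ("bin_count", "hz"):
            raise ValueError("band_weighting must be 'bin_count' or 'hz'")
        if self.columns_per_window < 8:
            raise ValueError(
                "analysis_window_s too short: fewer than 8 spectrogram "
                "columns, cannot form two Welch segments"
            )

    @property
    def column_rate(self) -> float:
        return self.sample_rate / (self.window_samples - self.overlap_samples)

    @property
    def columns_per_window(self) -> int:
        win = int(round(self.analysis_window_s * self.sample_rate))
        hop = self.window_samples - self.overlap_samples
        return (win - self.overlap_samples) // hop


@dataclass(frozen=True)
class AmplitudeSignal:
    """Clipped net band-energy time series, one value per spectrogram column."""

    values: np.ndarray
    rate: float  # columns per second

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("amplitude signal must be non-negative and finite")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PulseRateSpectrum:
    """Welch PSD of an amplitude signal: rate axis (Hz) and power."""

    rates: np.ndarray
    power: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.rates[1] - self.rates[0])

    def peak_rate(self, low: float, high: float) -> float:
        """Rate of the strongest bin with center in [low, high] (lowest tied)."""
        mask = (self.rates >= low) & (self.rates <= high)
        if not mask.any():
            idx = int(np.argmin(np.abs(self.rates - (low + high) / 2)))
            return float(self.rates[idx])
        sel = np.flatnonzero(mask)
        return float(self.rates[sel[np.argmax(self.power[sel])]])


@dataclass(frozen=True)
class ScoreSequence:
    """Per-analysis-window scores with their start times.

    ``filtered`` marks a sequence that has been through the continuity
    filter (length ``l - n + 1`` of the raw sequence).
    """

    scores: np.ndarray
    window_start_s: np.ndarray
    window_s: float
    filtered: bool = False
    source_path: str | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        starts = np.asarray(self.window_start_s, dtype=np.float64)
        if scores.shape != starts.shape:
            raise ValueError("scores and window_start_s must have equal length")
        if np.any(scores < 0):
            raise ValueError("scores must be non-negative")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "window_start_s", starts)

    def __len__(self) -> int:
        return len(self.scores)

    def aggregate(self, how: str = "max") -> float:
        """File-level score: max (default) or mean over windows."""
        if len(self.scores) == 0:
            raise ValueError("cannot aggregate an empty score sequence")
        if how == "max":
            return float(self.scores.max())
        if how == "mean":
            return float(self.scores.mean())
        raise ValueError(f"unknown aggregation {how!r}")


def amplitude_signal(
    spec: Spectrogram,
    signal_band: FrequencyBand,
    noise_bands: tuple[FrequencyBand, ...] | list[FrequencyBand] = (),
    weighting: str = "bin_count",
) -> AmplitudeSignal:
    """Net banded amplitude per spectrogram column, clipped at zero.

    With bin-count weighting, ``alpha = 1 / #signal bins`` and ``beta =
    1 / total #noise bins`` (across all noise bands), so a uniform
    spectrogram yields exactly zero net amplitude. A bin inside both the
    signal band and a noise band is added and subtracted. With no noise
    bands the beta term vanishes.
    """
    sig_rows = band_to_rows(spec, signal_band)
    noise_rows = [band_to_rows(spec, b) for b in noise_bands]
    n_noise = sum(r.size for r in noise_rows)

    if weighting == "bin_count":
        alpha = 1.0 / sig_rows.size if sig_rows.size else 0.0
        beta = 1.0 / n_noise if n_noise else 0.0
        bin_scale = 1.0
    elif weighting == "hz":
        alpha = 1.0 / signal_band.width_hz
        beta = (
            1.0 / sum(b.width_hz for b in noise_bands) if noise_bands else 0.0
        )
        bin_scale = spec.sample_rate / spec.window_samples  # Hz per bin
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    a = np.zeros(spec.n_columns)
    if sig_rows.size:
        a += alpha * bin_scale * spec.values[sig_rows].sum(axis=0)
    for rows in noise_rows:
        if rows.size:
            a -= beta * bin_scale * spec.values[rows].sum(axis=0)
    np.clip(a, 0.0, None, out=a)
    return AmplitudeSignal(a, rate=spec.column_rate)


def default_welch_segment(n_columns: int) -> int:
    """Largest power of two <= n_columns / 2 (>= 2 averaged segments)."""
    if n_columns < 8:
        raise ValueError("amplitude signal too short for Welch averaging")
    return 2 ** int(math.floor(math.log2(n_columns / 2)))


def pulse_rate_spectrum(
    amp: AmplitudeSignal,
    welch_segment_columns: int | None = None,
    welch_overlap_fraction: float = 0.5,
) -> PulseRateSpectrum:
    """Welch PSD of the amplitude signal.

    Hann-windowed segments with the given fractional overlap, no
    detrending, and "spectrum"-style (unnormalized) scaling. The rate axis
    runs from 0 to half the column rate.
    """
    nseg = welch_segment_columns or default_welch_segment(len(amp))
    if nseg < 4:
        raise ValueError("welch_segment_columns must be >= 4")
    if len(amp) < nseg:
        raise ValueError(
            f"amplitude signal of {len(amp)} columns is shorter than one "
            f"Welch segment ({nseg} columns = {nseg / amp.rate:.3f} s)"
        )
    rates, power = sps.welch(
        amp.values,
        fs=amp.rate,
        window="hann",
        nperseg=nseg,
        noverlap=int(round(nseg * welch_overlap_fraction)),
        detrend=False,
        scaling="spectrum",
    )
    return PulseRateSpectrum(rates=rates, power=power)


def ribbit_score(
    spectrum: PulseRateSpectrum, pulse_rate_range: tuple[float, float]
) -> float:
    """Maximum PSD value over rate bins with centers in ``[Rl, Rh]``.

    If no bin center falls inside the range (a misconfigured, very narrow
    range), the nearest bin is used and a warning issued.
    """
    rl, rh = pulse_rate_range
    if not 0 < rl < rh:
        raise ValueError("need 0 < Rl < Rh")
    mask = (spectrum.rates >= rl) & (spectrum.rates <= rh)
    if not mask.any():
        warnings.warn(
            f"no PSD bin center in [{rl}, {rh}] pps (bin width "
            f"{spectrum.bin_width:.3f}); using nearest bin",
            stacklevel=2,
        )
        idx = int(np.argmin(np.abs(spectrum.rates - (rl + rh) / 2)))
        return float(spectrum.power[idx])
    return float(spectrum.power[mask].max())


def score_clip(clip: AudioClip, profile: SpeciesProfile) -> float:
    """Score a single analysis-window-sized clip: one P value."""
    spec = compute_spectrogram(
        clip, profile.window_samples, profile.overlap_samples, profile.stft_window
    )
    amp = amplitude_signal(
        spec, profile.signal_band, profile.noise_bands, profile.band_weighting
    )
    spectrum = pulse_rate_spectrum(
        amp, profile.welch_segment_columns, profile.welch_overlap_fraction
    )
    return ribbit_score(spectrum, profile.pulse_rate_range)


def score_sequence(clip: AudioClip, profile: SpeciesProfile) -> ScoreSequence:
    """Score every analysis window of a clip (the sequence ``P_ss``).

    The clip is resampled to the profile's rate if needed, cut into
    non-overlapping ``analysis_window_s`` windows (trailing partial window
    dropped), and each window scored independently. Deterministic: no
    randomness anywhere in the scoring path.
    """
    if clip.sample_rate != profile.sample_rate:
        clip = resample(clip, profile.sample_rate)
    windows = segment(clip, profile.analysis_window_s)
    scores = np.array([score_clip(w, profile) for w in windows])
    starts = np.array([w.offset_s for w in windows])
    return ScoreSequence(
        scores=scores,
        window_start_s=starts,
        window_s=profile.analysis_window_s,
        source_path=clip.source_path,
    )


def continuity_filter(seq: ScoreSequence, n: int) -> ScoreSequence:
    """Forward-looking moving minimum over ``n`` consecutive windows.

    ``P_mm(i) = min(P_ss(i), ..., P_ss(i+n-1))`` for ``i = 0 .. l-n``;
    output length ``l - n + 1``, start times kept from index ``i``.
    ``n = 1`` is the identity (filter disabled).
    """
    l = len(seq)
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > l:
        raise ValueError(f"continuity filter length n={n} exceeds sequence length {l}")
    mm = np.lib.stride_tricks.sliding_window_view(seq.scores, n).min(axis=1)
    return replace(
        seq,
        scores=mm,
        window_start_s=seq.window_start_s[: l - n + 1],
        filtered=True,
    )
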