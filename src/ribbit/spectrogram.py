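"""Magnitude spectrograms with explicit axes, and band-to-bin mapping.

The detector works on a *linear magnitude* short-time Fourier transform
(not power, not dB): the banded sums that form the amplitude signal are
linear in pixel values, so a linear spectrogram gives the whole pipeline a
clean homogeneity property (scaling the audio by c scales every score by
c^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .audio_io import AudioClip

__all__ = [
    "FrequencyBand",
    "Spectrogram",
    "compute_spectrogram",
    "max_detectable_pulse_rate",
    "band_to_rows",
]


@dataclass(frozen=True)
class FrequencyBand:
    """Closed frequency interval [low_hz, high_hz] in Hz."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(f"invalid band [{self.low_hz}, {self.high_hz}]")

    @property
    def width_hz(self) -> float:
        return self.high_hz - self.low_hz


@dataclass(frozen=True)
class Spectrogram:
    """Frequency x time magnitude matrix with explicit axes.

    ``values[f, t]`` is the linear STFT magnitude at bin-center frequency
    ``freq_axis[f]`` and frame-center time ``time_axis[t]``. The column
    rate (frames per second) is ``sample_rate / (window_samples -
    overlap_samples)``; its Nyquist rate bounds the detectable pulse
    repetition rate.
    """

    values: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    window_samples: int
    overlap_samples: int
    sample_rate: float

    @property
    def column_rate(self) -> float:
        return self.sample_rate / (self.window_samples - self.overlap_samples)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def max_detectable_pulse_rate(
    sample_rate: float, window_samples: int, overlap_samples: int
) -> float:
    """Nyquist rate of the amplitude signal, in pulses per second.

    Each spectrogram column spans ``(window_samples - overlap_samples) /
    sample_rate`` seconds, so amplitude modulation is resolvable up to half
    the column rate — e.g. 62.5 pps for 32 kHz audio with 256-sample
    non-overlapping windows.
    """
    hop = window_samples - overlap_samples
    if hop <= 0:
        raise ValueError("overlap_samples must be smaller than window_samples")
    return (sample_rate / hop) / 2.0


def compute_spectrogram(
    clip: AudioClip,
    window_samples: int,
    overlap_samples: int = 0,
    window: str = "hann",
) -> Spectrogram:
    """Linear-magnitude STFT of a clip.

    Frames start at sample 0 and advance by ``window_samples -
    overlap_samples``; no padding, so the column count is
    ``floor((n - overlap) / (window - overlap))`` and a clip shorter than
    one window is an error. Frequency bins are at the transform's native
    resolution ``sample_rate / window_samples`` (no zero padding).
    """
    if not 0 <= overlap_samples < window_samples:
        raise ValueError("need 0 <= overlap_samples < window_samples")
    if len(clip.samples) < window_samples:
        raise ValueError(
            f"clip of {len(clip.samples)} samples is shorter than one "
            f"{window_samples}-sample spectrogram window"
        )
    freqs, times, mags = sps.spectrogram(
        clip.samples,
        fs=clip.sample_rate,
        window=window,
        nperseg=window_samples,
        noverlap=overlap_samples,
        detrend=False,
        scaling="spectrum",
        mode="magnitude",
    )
    return Spectrogram(
        values=mags,
        freq_axis=freqs,
        time_axis=times,
        window_samples=window_samples,
        overlap_samples=overlap_samples,
        sample_rate=clip.sample_rate,
    )


def band_to_rows(spec: Spectrogram, band: FrequencyBand) -> np.ndarray:
    """Indices of frequency bins whose center lies in ``band`` (edges inclusive).

    Overlapping bands are independent: a bin may belong to the signal band
    and a noise band at once. An empty result triggers a warning — a band
    with no bins contributes nothing to the amplitude signal.
    """
    nyquist = spec.sample_rate / 2.0
    if band.high_hz > nyquist:
        raise ValueError(
            f"band [{band.low_hz}, {band.high_hz}] exceeds Nyquist {nyquist} Hz"
        )
    rows = np.flatnonzero((spec.freq_axis >= band.low_hz) & (spec.freq_axis <= band.high_hz))
    if rows.size == 0:
        warnings.warn(
            f"band [{band.low_hz}, {band.high_hz}] Hz contains no bin centers "
            f"(bin spacing {spec.sample_rate / spec.window_samples:.1f} Hz); "
            "it will be ignored",
            stacklevel=2,
        )
    return rows
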