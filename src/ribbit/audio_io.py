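"""Reading, resampling, and segmenting audio.

All audio is carried as :class:`AudioClip`: a mono float array in [-1, 1]
full-scale with an explicit sample rate. WAV (RIFF) files with integer PCM
(8/16/24/32-bit) or IEEE float samples are supported; multi-channel files
are averaged to mono. Resampling is polyphase (band-limited), so no energy
is aliased into analysis bands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["AudioClip", "read_audio", "write_audio", "segment", "resample"]

# full-scale divisors per integer WAV dtype (uint8 is offset binary)
_PCM_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
}


@dataclass(frozen=True)
class AudioClip:
    """Mono audio: samples in [-1, 1] full scale plus a sample rate in Hz.

    Parameters
    ----------
    samples
        1-D float array of amplitudes.
    sample_rate
        Samples per second; must be positive.
    source_path
        Optional provenance (path of the file the clip came from).
    offset_s
        Seconds from the start of the source file to this clip's first sample.
    """

    samples: np.ndarray
    sample_rate: float
    source_path: str | None = None
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioClip samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioClip samples must be finite")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


def _to_float(data: np.ndarray) -> np.ndarray:
    """Scale raw WAV samples to [-1, 1] floats."""
    if data.dtype.kind == "f":
        return data.astype(np.float64)
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        return (data.astype(np.float64) - 128.0) / 128.0
    try:
        scale = _PCM_SCALE[data.dtype]
    except KeyError:  # pragma: no cover - wavfile only yields the above
        raise IOError(f"unsupported WAV sample format {data.dtype}")
    return data.astype(np.float64) / scale


def read_audio(path: str | Path, target_sample_rate: float | None = None) -> AudioClip:
    """Read a WAV file as a mono :class:`AudioClip`, optionally resampled.

    Multi-channel audio is averaged across channels. If
    ``target_sample_rate`` is given and differs from the native rate, the
    signal is resampled with a polyphase band-limited filter; otherwise the
    native samples pass through untouched (bit-identical for integer PCM).
    """
    path = Path(path)
    try:
        native_rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"could not read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty audio file: {path}")
    samples = _to_float(data)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    clip = AudioClip(samples, float(native_rate), source_path=str(path))
    if target_sample_rate is not None and target_sample_rate != native_rate:
        clip = resample(clip, target_sample_rate)
    return clip


def write_audio(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as an IEEE-float32 WAV file."""
    wavfile.write(Path(path), int(round(clip.sample_rate)), clip.samples.astype(np.float32))


def resample(clip: AudioClip, target_sample_rate: float) -> AudioClip:
    """Polyphase resampling to ``target_sample_rate``."""
    if target_sample_rate <= 0:
        raise ValueError("target_sample_rate must be positive")
    if target_sample_rate == clip.sample_rate:
        return clip
    ratio = Fraction(target_sample_rate / clip.sample_rate).limit_denominator(10_000)
    out = resample_poly(clip.samples, ratio.numerator, ratio.denominator)
    return replace(clip, samples=out, sample_rate=float(target_sample_rate))


def segment(clip: AudioClip, window_s: float) -> list[AudioClip]:
    """Cut a clip into consecutive non-overlapping windows of ``window_s``.

    Returns ``floor(duration / window_s)`` clips; a trailing partial window
    is dropped (a short window would change the statistical basis of the
    per-window score). A clip shorter than one window yields an empty list.
    Each output clip's ``offset_s`` is its start time relative to the
    original clip's source.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    win = int(round(window_s * clip.sample_rate))
    n = len(clip.samples) // win if win > 0 else 0
    out = []
    for i in range(n):
        out.append(
            AudioClip(
                clip.samples[i * win : (i + 1) * win],
                clip.sample_rate,
                source_path=clip.source_path,
                offset_s=clip.offset_s + i * window_s,
            )
        )
    return out
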