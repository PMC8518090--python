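"""Seeded synthetic soundscapes with known ground truth.

Field recordings used to develop pulse-rate detectors are rarely
redistributable, so every pipeline stage here is exercised on synthetic
audio instead: amplitude-modulated pulse trains standing in for anuran
choruses, plus the nuisance classes that cause false positives in practice
— rain-like broadband clicks, continuous narrow-band tones (toad-like
calls), and short pulsed bird-like syllable bursts.

The pulse-train carrier is band-limited noise rather than a harmonic
stack: the detector only measures periodic amplitude modulation inside the
signal band, and a noise carrier avoids accidental alignment of harmonics
with PSD bins. Modulation is rectangular with a configurable duty cycle
(``envelope="rect"``); a raised-cosine envelope is available for smoother
onsets.

Every generator is a pure function of its spec and seed: same arguments,
bit-identical audio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import AudioClip, write_audio
from .spectrogram import FrequencyBand

__all__ = [
    "PulseTrainSpec",
    "ConfuserSpec",
    "gen_pulse_train",
    "gen_background",
    "gen_confusers",
    "write_fixture_set",
]


@dataclass(frozen=True)
class PulseTrainSpec:
    """Ground-truth description of a synthetic pulsed call.

    ``pulse_rate_pps`` is the amplitude-modulation rate; ``carrier_band``
    holds the spectral energy; ``duty_cycle`` is the on-fraction of each
    modulation period; ``rms_level`` is the target RMS in full-scale
    units.
    """

    pulse_rate_pps: float
    carrier_band: FrequencyBand
    duty_cycle: float = 0.5
    duration_s: float = 10.0
    rms_level: float = 0.1
    seed: int = 0
    envelope: str = "rect"  # or "raised_cosine"

    def __post_init__(self) -> None:
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty_cycle must lie strictly between 0 and 1")
        if self.pulse_rate_pps <= 0:
            raise ValueError("pulse_rate_pps must be positive")


def _band_noise(
    rng: np.random.Generator, n: int, sample_rate: float, band: FrequencyBand
) -> np.ndarray:
    """White noise brick-wall filtered to ``band`` via the real FFT."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    spec[(freqs < band.low_hz) | (freqs > band.high_hz)] = 0.0
    return np.fft.irfft(spec, n=n)


def _set_rms(x: np.ndarray, rms_level: float) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        return x
    return x * (rms_level / rms)


def gen_pulse_train(spec: PulseTrainSpec, sample_rate: float) -> AudioClip:
    """Band-limited noise carrier amplitude-modulated at a known pulse rate."""
    if spec.carrier_band.high_hz > sample_rate / 2:
        raise ValueError(
            f"carrier band {spec.carrier_band} exceeds Nyquist {sample_rate / 2} Hz"
        )
    if spec.pulse_rate_pps >= sample_rate / 2:
        raise ValueError("pulse rate must be below audio Nyquist")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * sample_rate))
    carrier = _band_noise(rng, n, sample_rate, spec.carrier_band)
    t = np.arange(n) / sample_rate
    phase = (t * spec.pulse_rate_pps) % 1.0
    if spec.envelope == "rect":
        env = (phase < spec.duty_cycle).astype(np.float64)
    elif spec.envelope == "raised_cosine":
        env = np.where(
            phase < spec.duty_cycle,
            0.5 - 0.5 * np.cos(2 * np.pi * phase / spec.duty_cycle),
            0.0,
        )
    else:
        raise ValueError(f"unknown envelope {spec.envelope!r}")
    return AudioClip(_set_rms(carrier * env, spec.rms_level), sample_rate)


def gen_background(
    kind: str,
    duration_s: float,
    rms_level: float,
    seed: int,
    sample_rate: float = 32000.0,
) -> AudioClip:
    """Seeded white or pink (power ~ 1/f) background noise at a target RMS."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    x = rng.standard_normal(n)
    if kind == "pink":
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
        shaping = np.zeros_like(freqs)
        shaping[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude 1/sqrt(f) => power 1/f
        x = np.fft.irfft(spec * shaping, n=n)
    elif kind != "white":
        raise ValueError("kind must be 'white' or 'pink'")
    return AudioClip(_set_rms(x, rms_level), sample_rate)


@dataclass(frozen=True)
class ConfuserSpec:
    """Gains and timing for the three nuisance components.

    * ``click_gain``: broadband impulsive clicks at Poisson times
      (rain on the microphone).
    * ``tone_gain``: a continuous tone inside 1800-2500 Hz (narrow-band
      toad-like call).
    * ``burst_gain``: short pulsed syllable bursts separated by silence
      (bird-like; pulses at ``burst_pulse_rate_pps``).
    """

    click_gain: float = 1.0
    click_rate_per_s: float = 3.0
    tone_gain: float = 1.0
    tone_hz: float = 2150.0
    burst_gain: float = 1.0
    burst_pulse_rate_pps: float = 15.0
    burst_on_s: float = 4.0
    burst_off_s: float = 10.0
    rms_level: float = 0.1


def gen_confusers(
    duration_s: float,
    seed: int,
    sample_rate: float = 32000.0,
    spec: ConfuserSpec = ConfuserSpec(),
) -> tuple[AudioClip, pd.DataFrame]:
    """Mix of nuisance sounds plus a ground-truth event table.

    Returns the clip and a DataFrame with columns ``kind``,
    ``event_start_s``, ``event_end_s``, ``true_pulse_rate_pps`` (NaN for
    aperiodic components). Component gains of zero drop that component.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.zeros(n)
    events: list[dict] = []

    if spec.click_gain > 0:
        n_clicks = rng.poisson(spec.click_rate_per_s * duration_s)
        click_times = np.sort(rng.uniform(0, duration_s, n_clicks))
        click_len = int(0.002 * sample_rate)  # 2 ms broadband pop
        for ct in click_times:
            i0 = int(ct * sample_rate)
            seg = rng.standard_normal(min(click_len, n - i0))
            seg *= np.hanning(len(seg)) if len(seg) > 2 else 1.0
            x[i0 : i0 + len(seg)] += spec.click_gain * seg
            events.append(
                dict(kind="click", event_start_s=ct, event_end_s=ct + 0.002,
                     true_pulse_rate_pps=np.nan)
            )

    if spec.tone_gain > 0:
        x += spec.tone_gain * 0.3 * np.sin(2 * np.pi * spec.tone_hz * t)
        events.append(
            dict(kind="tone", event_start_s=0.0, event_end_s=duration_s,
                 true_pulse_rate_pps=np.nan)
        )

    if spec.burst_gain > 0:
        period = spec.burst_on_s + spec.burst_off_s
        start = 0.0
        while start < duration_s:
            end = min(start + spec.burst_on_s, duration_s)
            i0, i1 = int(start * sample_rate), int(end * sample_rate)
            burst = gen_pulse_train(
                PulseTrainSpec(
                    pulse_rate_pps=spec.burst_pulse_rate_pps,
                    carrier_band=FrequencyBand(1500, 6000),
                    duration_s=(i1 - i0) / sample_rate,
                    rms_level=0.3,
                    seed=int(rng.integers(2**31)),
                ),
                sample_rate,
            )
            x[i0:i1] += spec.burst_gain * burst.samples[: i1 - i0]
            events.append(
                dict(kind="burst", event_start_s=start, event_end_s=end,
                     true_pulse_rate_pps=spec.burst_pulse_rate_pps)
            )
            start += period

    clip = AudioClip(_set_rms(x, spec.rms_level), sample_rate)
    return clip, pd.DataFrame(
        events, columns=["kind", "event_start_s", "event_end_s", "true_pulse_rate_pps"]
    )


def write_fixture_set(
    out_dir: str | Path,
    seed: int,
    n_positive: int = 5,
    n_negative: int = 5,
    duration_s: float = 30.0,
    sample_rate: float = 32000.0,
) -> pd.DataFrame:
    """Write a labelled WAV fixture set plus a ground-truth CSV.

    Positives are continuous 15-pps pulse trains in the 1.5-6 kHz chorus
    band over pink background; negatives cycle through the nuisance
    classes. Returns the ground-truth table (also written to
    ``ground_truth.csv``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_positive):
        clip = mix_clips(
            gen_pulse_train(
                PulseTrainSpec(
                    pulse_rate_pps=15.0,
                    carrier_band=FrequencyBand(1500, 6000),
                    duration_s=duration_s,
                    rms_level=0.1,
                    seed=int(rng.integers(2**31)),
                ),
                sample_rate,
            ),
            gen_background("pink", duration_s, 0.02, int(rng.integers(2**31)), sample_rate),
        )
        name = f"positive_{i:02d}.wav"
        write_audio(out / name, clip)
        rows.append(dict(file=name, event_start_s=0.0, event_end_s=duration_s,
                         true_pulse_rate_pps=15.0))
    kinds = [
        ConfuserSpec(tone_gain=0.0, burst_gain=0.0),
        ConfuserSpec(click_gain=0.0, burst_gain=0.0),
        ConfuserSpec(click_gain=0.0, tone_gain=0.0),
    ]
    for i in range(n_negative):
        clip, _ = gen_confusers(
            duration_s, int(rng.integers(2**31)), sample_rate, kinds[i % len(kinds)]
        )
        name = f"negative_{i:02d}.wav"
        write_audio(out / name, clip)
        rows.append(dict(file=name, event_start_s=np.nan, event_end_s=np.nan,
                         true_pulse_rate_pps=np.nan))
    truth = pd.DataFrame(rows)
    truth.to_csv(out / "ground_truth.csv", index=False)
    return truth


def mix_clips(*clips: AudioClip) -> AudioClip:
    """Sum equally-long clips sharing a sample rate."""
    first = clips[0]
    if any(len(c) != len(first) or c.sample_rate != first.sample_rate for c in clips):
        raise ValueError("clips must share length and sample rate")
    return AudioClip(np.sum([c.samples for c in clips], axis=0), first.sample_rate)
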