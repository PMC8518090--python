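"""Species profiles: flat YAML serialization and the two shipped configs.

A profile file mirrors the analysis-parameter table for a species::

    name: boreal_chorus_frog
    sample_rate_hz: 32000
    window_samples: 256
    overlap_samples: 0
    signal_band_hz: [1000, 3300]
    noise_bands_hz: [[100, 1000], [1800, 2500]]
    pulse_rate_hz: [13, 30]
    analysis_window_s: 2.0
    continuity_n: 10

Shipped profiles: ``boreal_chorus_frog`` (*Pseudacris maculata*; 13-30 pps
advertisement-call pulse range, noise bands against wind and narrow-band
toad calls) and ``variable_harlequin_frog`` (*Atelopus varius*; ~130 pps
amplitude modulation, searched at 120-150 pps with a 0.5 s window and no
continuity filter).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .core import SpeciesProfile
from .spectrogram import FrequencyBand

__all__ = ["load_profile", "save_profile", "builtin_profiles"]

_OPTIONAL_KEYS = (
    "welch_segment_columns",
    "welch_overlap_fraction",
    "band_weighting",
    "stft_window",
)


def _from_dict(data: dict) -> SpeciesProfile:
    kwargs = {k: data[k] for k in _OPTIONAL_KEYS if k in data}
    return SpeciesProfile(
        signal_band=FrequencyBand(*data["signal_band_hz"]),
        noise_bands=tuple(FrequencyBand(*b) for b in data.get("noise_bands_hz", [])),
        pulse_rate_range=tuple(float(r) for r in data["pulse_rate_hz"]),
        analysis_window_s=float(data["analysis_window_s"]),
        continuity_n=int(data.get("continuity_n", 1)),
        window_samples=int(data["window_samples"]),
        overlap_samples=int(data.get("overlap_samples", 0)),
        sample_rate=float(data["sample_rate_hz"]),
        name=data.get("name"),
        **kwargs,
    )


def load_profile(source: str | Path) -> SpeciesProfile:
    """Load a profile from a YAML file path or a built-in profile name."""
    path = Path(source)
    if not path.exists():
        builtin = resources.files(__package__) / "profiles" / f"{source}.yaml"
        if builtin.is_file():
            return _from_dict(yaml.safe_load(builtin.read_text()))
        raise FileNotFoundError(
            f"profile {source!r} is neither a file nor a built-in profile "
            f"({', '.join(builtin_profiles())})"
        )
    return _from_dict(yaml.safe_load(path.read_text()))


def save_profile(profile: SpeciesProfile, path: str | Path) -> None:
    data: dict = {
        "name": profile.name,
        "sample_rate_hz": profile.sample_rate,
        "window_samples": profile.window_samples,
        "overlap_samples": profile.overlap_samples,
        "signal_band_hz": [profile.signal_band.low_hz, profile.signal_band.high_hz],
        "noise_bands_hz": [[b.low_hz, b.high_hz] for b in profile.noise_bands],
        "pulse_rate_hz": list(profile.pulse_rate_range),
        "analysis_window_s": profile.analysis_window_s,
        "continuity_n": profile.continuity_n,
    }
    for key in _OPTIONAL_KEYS:
        value = getattr(profile, key)
        if value is not None:
            data[key] = value
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def builtin_profiles() -> list[str]:
    """Names of profiles shipped with the package."""
    pkg = resources.files(__package__) / "profiles"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir() if p.name.endswith(".yaml"))
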