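"""Score a synthetic frog chorus against the boreal chorus frog profile.

Builds 10 s of a 15-pulses-per-second amplitude-modulated chorus in the
1.5-6 kHz band over pink background noise, plus an equal-RMS noise-only
clip, and prints the per-window scores. The pulsed clip should score
orders of magnitude above the noise: the score is the peak power spectral
density of the band-limited amplitude envelope inside the 13-30 pps
search range.
"""

import numpy as np

from ribbit import (
    FrequencyBand,
    PulseTrainSpec,
    gen_background,
    gen_pulse_train,
    load_profile,
    mix_clips,
    score_sequence,
)

profile = load_profile("boreal_chorus_frog")

chorus = mix_clips(
    gen_pulse_train(
        PulseTrainSpec(
            pulse_rate_pps=15.0,
            carrier_band=FrequencyBand(1500, 6000),
            duration_s=10.0,
            rms_level=0.1,
            seed=1,
        ),
        profile.sample_rate,
    ),
    gen_background("pink", 10.0, 0.02, seed=2, sample_rate=profile.sample_rate),
)
noise = gen_background("pink", 10.0, 0.1, seed=3, sample_rate=profile.sample_rate)

for name, clip in [("chorus", chorus), ("noise-only", noise)]:
    seq = score_sequence(clip, profile)
    windows = ", ".join(f"{s:.2e}" for s in seq.scores)
    print(f"{name:11s} windows: [{windows}]")
    print(f"{name:11s} file score (max): {seq.aggregate('max'):.2e}")

print(
    "\nEach value is one 2-s analysis window; the pulsed chorus scores "
    "~4 orders of magnitude above equal-RMS pink noise."
)
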