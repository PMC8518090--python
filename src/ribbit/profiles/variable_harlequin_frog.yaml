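name: variable_harlequin_frog
sample_rate_hz: 22050
window_samples: 32
overlap_samples: 16
signal_band_hz: [1500, 2500]
noise_bands_hz: [[0, 1000], [3500, 4000]]
pulse_rate_hz: [120, 150]
analysis_window_s: 0.5
continuity_n: 1
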