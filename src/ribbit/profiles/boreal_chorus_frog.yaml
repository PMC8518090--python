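name: boreal_chorus_frog
sample_rate_hz: 32000
window_samples: 256
overlap_samples: 0
signal_band_hz: [1000, 3300]
noise_bands_hz: [[100, 1000], [1800, 2500]]
pulse_rate_hz: [13, 30]
analysis_window_s: 2.0
continuity_n: 10
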