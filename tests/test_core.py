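"""The scoring pipeline: amplitude signal, PSD, score, continuity filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribbit import (
    AmplitudeSignal,
    AudioClip,
    FrequencyBand,
    PulseTrainSpec,
    ScoreSequence,
    SpeciesProfile,
    amplitude_signal,
    continuity_filter,
    gen_background,
    gen_pulse_train,
    mix_clips,
    pulse_rate_spectrum,
    ribbit_score,
    score_sequence,
)


class TestAmplitudeSignal:
    def test_hand_computed_band_sums(self, toy_spectrogram, toy_bands):
        # column [1,4,6,2]: (4+6)/2 - (1+2)/2 = 3.5
        # column [5,1,1,5]: 1 - 5 = -4 -> clipped to 0
        spec = toy_spectrogram([[1, 4, 6, 2], [5, 1, 1, 5]])
        amp = amplitude_signal(spec, toy_bands["signal"], toy_bands["noise"])
        assert amp.values == pytest.approx([3.5, 0.0])
        assert amp.rate == pytest.approx(4.0)

    def test_uniform_spectrogram_cancels_exactly(self, toy_spectrogram, toy_bands):
        spec = toy_spectrogram([[7.0] * 4] * 5)
        amp = amplitude_signal(spec, toy_bands["signal"], toy_bands["noise"])
        assert np.all(amp.values == 0)

    def test_no_noise_bands_gives_signal_band_mean(self, toy_spectrogram):
        spec = toy_spectrogram([[1, 2, 3, 4], [4, 8, 12, 16]])
        amp = amplitude_signal(spec, FrequencyBand(0, 3.5), ())
        assert amp.values == pytest.approx([2.5, 10.0])

    def test_hz_weighting_matches_bin_counts_on_aligned_bands(self, boreal):
        clip = gen_pulse_train(
            PulseTrainSpec(15, FrequencyBand(1500, 6000), duration_s=2, seed=4), 32000
        )
        from ribbit import compute_spectrogram

        spec = compute_spectrogram(clip, boreal.window_samples, boreal.overlap_samples)
        by_bins = amplitude_signal(spec, boreal.signal_band, boreal.noise_bands, "bin_count")
        by_hz = amplitude_signal(spec, boreal.signal_band, boreal.noise_bands, "hz")
        # bands share bin spacing alignment only approximately; shapes must agree
        corr = np.corrcoef(by_bins.values, by_hz.values)[0, 1]
        assert corr > 0.99

    def test_negative_values_rejected_in_type(self):
        with pytest.raises(ValueError):
            AmplitudeSignal(np.array([1.0, -0.1]), rate=125.0)


class TestPulseRateSpectrum:
    def test_zero_signal_zero_power(self):
        spectrum = pulse_rate_spectrum(AmplitudeSignal(np.zeros(256), 125.0), 64)
        assert np.all(spectrum.power == 0)

    def test_sinusoidal_modulation_peaks_at_its_rate(self):
        # 1 + sin(2*pi*15*t) at 125 columns/s; 50-column Welch segments put
        # 15 Hz on a bin center (2.5 Hz bins)
        t = np.arange(250) / 125.0
        amp = AmplitudeSignal(1 + np.sin(2 * np.pi * 15 * t), 125.0)
        spectrum = pulse_rate_spectrum(amp, 50)
        # beyond the Hann DC main lobe the sine bin dominates
        peak = spectrum.peak_rate(5.0, 62.5)
        assert abs(peak - 15.0) <= spectrum.bin_width
        # closed forms: DC bin = mean^2, sine bin = amplitude^2 / 2
        assert spectrum.power[0] == pytest.approx(1.0, rel=1e-9)
        idx = int(np.argmin(np.abs(spectrum.rates - 15.0)))
        assert spectrum.power[idx] == pytest.approx(0.5, rel=1e-9)

    def test_dc_signal_concentrates_at_zero(self):
        spectrum = pulse_rate_spectrum(AmplitudeSignal(np.full(256, 3.0), 125.0), 64)
        assert spectrum.power[0] == spectrum.power.max()
        assert spectrum.power[3:].max() < 1e-12 * spectrum.power[0]

    def test_too_short_signal_names_minimum(self):
        with pytest.raises(ValueError, match="shorter than one Welch segment"):
            pulse_rate_spectrum(AmplitudeSignal(np.ones(16), 125.0), 64)


class TestRibbitScore:
    def test_max_over_in_range_bins(self):
        from ribbit.core import PulseRateSpectrum

        spectrum = PulseRateSpectrum(
            rates=np.array([0.0, 10.0, 15.0, 20.0, 25.0]),
            power=np.array([9.0, 0.2, 0.9, 0.5, 0.1]),
        )
        assert ribbit_score(spectrum, (13, 30)) == pytest.approx(0.9)

    def test_all_zero_spectrum_scores_zero(self):
        from ribbit.core import PulseRateSpectrum

        spectrum = PulseRateSpectrum(rates=np.linspace(0, 62.5, 33), power=np.zeros(33))
        assert ribbit_score(spectrum, (13, 30)) == 0.0

    def test_widening_range_never_decreases_score(self):
        rng = np.random.default_rng(5)
        from ribbit.core import PulseRateSpectrum

        spectrum = PulseRateSpectrum(
            rates=np.linspace(0, 62.5, 101), power=rng.uniform(0, 1, 101)
        )
        narrow = ribbit_score(spectrum, (13, 30))
        wide = ribbit_score(spectrum, (10, 40))
        assert wide >= narrow

    def test_empty_range_uses_nearest_bin_with_warning(self):
        from ribbit.core import PulseRateSpectrum

        spectrum = PulseRateSpectrum(
            rates=np.array([0.0, 10.0, 20.0]), power=np.array([1.0, 0.5, 0.2])
        )
        with pytest.warns(UserWarning, match="nearest bin"):
            assert ribbit_score(spectrum, (13.0, 14.0)) == pytest.approx(0.5)


class TestScoreSequence:
    def test_sixty_second_clip_boreal_yields_30_scores(self, boreal):
        clip = gen_background("pink", 60.0, 0.05, 7, 32000)
        seq = score_sequence(clip, boreal)
        assert len(seq) == 30
        assert seq.window_start_s == pytest.approx(np.arange(30) * 2.0)

    def test_pulse_train_outscores_equal_rms_noise(self, boreal):
        train = gen_pulse_train(
            PulseTrainSpec(15, FrequencyBand(1000, 3300), duration_s=10, rms_level=0.1, seed=8),
            32000,
        )
        noise = gen_background("white", 10.0, 0.1, 9, 32000)
        s_train = score_sequence(train, boreal).scores
        s_noise = score_sequence(noise, boreal).scores
        assert np.median(s_train) > np.median(s_noise)
        assert s_train.min() > s_noise.max()

    def test_homogeneity_scores_scale_as_c_squared(self, boreal):
        clip = mix_clips(
            gen_pulse_train(
                PulseTrainSpec(15, FrequencyBand(1500, 6000), duration_s=4, rms_level=0.05, seed=10),
                32000,
            ),
            gen_background("pink", 4.0, 0.01, 11, 32000),
        )
        scaled = AudioClip(2.0 * clip.samples, clip.sample_rate)
        base = score_sequence(clip, boreal).scores
        quad = score_sequence(scaled, boreal).scores
        assert quad == pytest.approx(4.0 * base, rel=1e-6)

    def test_noise_band_tone_never_raises_score(self, boreal):
        base = mix_clips(
            gen_pulse_train(
                PulseTrainSpec(15, FrequencyBand(1000, 3300), duration_s=4, rms_level=0.08, seed=12),
                32000,
            ),
            gen_background("pink", 4.0, 0.02, 13, 32000),
        )
        t = np.arange(len(base)) / base.sample_rate
        tone = AudioClip(0.1 * np.sin(2 * np.pi * 2100 * t), base.sample_rate)  # in 1800-2500
        with_tone = mix_clips(base, tone)
        assert np.all(
            score_sequence(with_tone, boreal).scores
            <= score_sequence(base, boreal).scores * (1 + 1e-9) + 1e-30
        )

    def test_resamples_clip_at_foreign_rate(self, boreal):
        clip = gen_background("white", 2.0, 0.1, 14, 16000)
        seq = score_sequence(clip, boreal)
        assert len(seq) == 1

    def test_determinism_bit_identical(self, boreal):
        clip = gen_pulse_train(
            PulseTrainSpec(20, FrequencyBand(1000, 3300), duration_s=4, seed=15), 32000
        )
        a = score_sequence(clip, boreal).scores
        b = score_sequence(clip, boreal).scores
        assert np.array_equal(a, b)


class TestContinuityFilter:
    def _seq(self, scores):
        scores = np.asarray(scores, dtype=float)
        return ScoreSequence(
            scores=scores,
            window_start_s=np.arange(len(scores)) * 2.0,
            window_s=2.0,
        )

    def test_worked_example(self):
        out = continuity_filter(self._seq([3, 1, 2, 5]), 2)
        assert out.scores == pytest.approx([1, 1, 2])
        assert out.filtered
        assert out.window_start_s == pytest.approx([0.0, 2.0, 4.0])

    def test_n1_is_identity(self):
        seq = self._seq([4, 2, 7])
        out = continuity_filter(seq, 1)
        assert np.array_equal(out.scores, seq.scores)

    def test_n_longer_than_sequence_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            continuity_filter(self._seq([1, 2]), 3)

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(
        scores=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=40),
        data=st.data(),
    )
    def test_matches_brute_force_minimum(self, scores, data):
        n = data.draw(st.integers(1, len(scores)))
        out = continuity_filter(self._seq(scores), n).scores
        expected = [min(scores[i : i + n]) for i in range(len(scores) - n + 1)]
        assert out.tolist() == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        scores=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=30),
        data=st.data(),
    )
    def test_filtered_value_bounds_every_window_member(self, scores, data):
        n = data.draw(st.integers(1, len(scores)))
        out = continuity_filter(self._seq(scores), n).scores
        for i, value in enumerate(out):
            assert all(value <= scores[j] for j in range(i, i + n))


class TestSpeciesProfile:
    def test_pulse_range_must_fit_under_amplitude_nyquist(self, boreal):
        with pytest.raises(ValueError, match="Nyquist"):
            SpeciesProfile(
                signal_band=boreal.signal_band,
                noise_bands=boreal.noise_bands,
                pulse_rate_range=(13.0, 80.0),  # > 62.5 pps ceiling
                analysis_window_s=2.0,
                continuity_n=10,
                window_samples=256,
                overlap_samples=0,
                sample_rate=32000,
            )

    def test_bands_must_fit_under_audio_nyquist(self, boreal):
        with pytest.raises(ValueError, match="Nyquist"):
            SpeciesProfile(
                signal_band=FrequencyBand(1000, 20000),
                noise_bands=(),
                pulse_rate_range=(13.0, 30.0),
                analysis_window_s=2.0,
                continuity_n=1,
                window_samples=256,
                overlap_samples=0,
                sample_rate=32000,
            )
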