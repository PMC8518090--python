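# Methods

## The detection model

The detector treats a species' call as periodic amplitude modulation of
band-limited energy. It makes three assumptions: (1) the focal species'
energy is concentrated in a known signal band; (2) within a detection
event the pulse repetition rate stays inside a known range `[R_l, R_h]`;
(3) the modulation persists for at least one analysis window (and, when
the continuity filter is used, for `n` consecutive windows). Nothing about
the spectral fine structure inside the band is used, which is what lets a
blended chorus of many callers still be detected: the aggregate keeps the
species' pulse rate even when individual calls overlap.

The pipeline per analysis window:

1. Linear-magnitude STFT `S[f, t]`. Magnitude (not power, not dB) is
   deliberate: the banded sums in step 2 are then linear in the audio
   amplitude, negative values of the net signal have a consistent meaning,
   and the end-to-end score scales exactly as `c²` when the audio scales
   by `c` — a property the test suite pins to 1e-6 relative tolerance.
2. Amplitude signal `a_net(t)`: the signal-band column sum minus the
   noise-band column sums, weighted so the two maximum possible
   contributions are equal, clipped at zero. Clipping means a noise band
   can only ever *reduce* the signal — adding sound inside a noise band
   never raises a score.
3. Welch PSD of `a_net` at the spectrogram column rate; the score is the
   PSD maximum over bins whose center lies in `[R_l, R_h]` (both edges
   inclusive; for a reported peak rate, ties resolve to the lowest rate).

### Band weighting

The normalizers are defined on frequency *ranges* (`α = 1/(f_s1 − f_s0)`,
`β = 1/Σ noise widths`). On a discrete spectrogram we default to the
bin-count realization — `α = 1/#signal bins`, `β = 1/#noise bins` — which
makes the equal-maximum-contribution property exact for the sums actually
computed: a uniform spectrogram cancels to exactly zero. A
`band_weighting: hz` profile flag switches to the literal reciprocal Hz
ranges (band sums multiplied by the bin width) for cross-checking; the two
agree when band edges align with bin boundaries. Band membership is by bin
center, both edges inclusive; bands may overlap (the shipped boreal
profile nests a noise band inside the signal band), and a bin in both is
added and subtracted. A band containing no bin centers contributes nothing
and triggers a warning — the shipped harlequin profile's 3500–4000 Hz
noise band is such a case at its 689 Hz bin spacing, and is kept verbatim
from the published parameter set.

### Welch parameters

The PSD segment length is not part of the published parameter set, so
results at field scale are property-reproducible rather than
bit-reproducible against other implementations. Defaults: Hann window,
segment length `2^floor(log2(L/2))` columns for an `L`-column amplitude
signal (guaranteeing at least two averaged segments; 64 columns for the
boreal profile's 250-column windows, giving ~1.95 Hz rate resolution),
50% overlap, no detrending, "spectrum"-style (unnormalized) scaling. All
are overridable per profile. Analysis windows must span at least 8
spectrogram columns so two 4-column Welch segments exist.

## Parameters that matter

| Parameter | Unit | Role | Shipped values (boreal / harlequin) |
|---|---|---|---|
| `sample_rate` | Hz | audio rate the profile is defined at | 32000 / 22050 |
| `window_samples`, `overlap_samples` | samples | STFT framing; hop sets the pulse-rate ceiling `fs/hop/2` | 256, 0 (62.5 pps) / 32, 16 (689 pps) |
| `signal_band` | Hz | positive contribution | 1000–3300 / 1500–2500 |
| `noise_bands` | Hz | subtracted contribution | 100–1000 & 1800–2500 / 0–1000 & 3500–4000 |
| `pulse_rate_range` | pps | PSD search range | 13–30 / 120–150 |
| `analysis_window_s` | s | one score per window | 2 / 0.5 |
| `continuity_n` | windows | moving-minimum length; 1 = off | 10 / 1 |

The boreal profile's 13–30 pps search range is the published analysis
value; the species' advertisement call is usually described as 10–20 pps,
and we ship the analysis value unchanged.

## Synthetic soundscapes

The generator emulates the structures that matter to this detector, not
species-realistic calls. Positives are rectangular-envelope pulse trains
(known rate, duty cycle 0.5 by default) modulating a band-limited noise
carrier — noise rather than harmonics so no harmonic accidentally aligns
with a PSD bin. Nuisance classes mirror the failure modes seen in field
audio: Poisson-timed broadband clicks (rain on the microphone), a
continuous narrow tone inside 1800–2500 Hz (narrow-band toad-like calls),
and short pulsed syllable bursts separated by silence (bird-like; these
share the target pulse rate and are rejected only by the continuity
filter). Backgrounds are white or pink (power ∝ 1/f) noise at specified
RMS. Every generator is a pure function of (spec, seed).

What passing synthetic tests does **not** show: robustness to reverberant
propagation, overlapping heterospecific choruses, pulse-rate drift with
temperature, wind-dominated low-frequency noise, or recorder artifacts.
Field thresholds must still be chosen on labeled field data — the package
exports score histograms and precision–recall sweeps for that purpose and
deliberately does not automate "natural break" threshold selection.

## Evaluation conventions

A file's score is the maximum over its (continuity-filtered, when
enabled) window scores — the "any window fired" statistic; `mean` is
available as an alternative aggregation. Detection uses `score ≥
threshold` (ties detect), so a published threshold keeps its meaning.
Precision with zero predicted positives is reported as NaN, never a
silent 0; F1 is 0 when precision and recall are both 0. Reported metrics
round half-up to two decimals. The dBFS convention is
`20·log10(2·rms)` (an rms of 0.5 reads 0 dBFS), and the dBA estimate
`dbfs(clip) − offset` is documented as coarse: it assumes the soundscape
approximates the calibration noise's spectrum and gain.

## Numerical and design choices

- **Framing**: STFT frames start at sample 0, no padding; column count is
  `floor((N − overlap)/hop)`. Trailing partial analysis windows are
  dropped, not padded (a short window would change the PSD's statistical
  basis).
- **Resampling**: polyphase (`resample_poly`) with the rational rate
  ratio; aliasing would otherwise leak energy across band edges. Batch
  scanning memory-maps the WAV and resamples window by window, so memory
  stays proportional to one analysis window; since analysis windows are
  non-overlapping and independent, per-window resampling only perturbs a
  few filter-edge samples relative to whole-file resampling (the streamed
  and in-memory paths agree to 1e-9 relative in the tests).
- **Multi-channel audio** is averaged to mono; the algorithm is defined on
  one channel and field recorders are mono.
- **Scoring is deterministic**: no randomness anywhere in the scoring
  path; all synthetic generation takes explicit seeds.
- **Degenerate inputs**: zero-length audio, clips shorter than one STFT
  window, amplitude signals shorter than one Welch segment, and a
  continuity length exceeding the sequence are errors that name the
  offending size; an empty pulse-rate search range falls back to the
  nearest bin with a warning.

## Problem sizes in the checks

The acceptance script and test suite run entirely on synthetic audio at
desk scale, as the package's own standard check sizes: the benchmark uses
16 thirty-second clips (8 pulse-train positives, 8 negatives across four
nuisance classes) at a shared 0.1 full-scale RMS; pulse-rate recovery uses
3 trials per rate on a 9-point grid across 13–30 pps (boreal) and a
7-point grid across 120–150 pps (harlequin) at 10 dB SNR over pink
background; homogeneity checks scales c ∈ {0.5, 2, 10} on a 6-s clip. The
published field-scale results (hundreds of labeled files, thousands of
recorded hours) depend on recordings that are not redistributable and are
out of scope here.

## Known limitations

- Fixed pulse rate only: systematically accelerating or decelerating
  displays (e.g. ruffed grouse drumming) would need a time-warp of the
  amplitude signal that this package does not implement.
- The score's absolute scale depends on the Welch configuration, so
  thresholds are not transferable between profiles or implementations
  with different PSD settings.
- WAV input only; compressed formats are out of scope.
- The dBA estimate is uncalibrated and coarse by construction.
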