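# Methods

`songeng` re-implements, as a tested pipeline over synthetic data, the
analysis chain of a chronic peripheral-nerve-interface experiment in
singing birds: vocal behavior is quantified by an acoustic-similarity
statistic; the multichannel electroneurogram (ENG) recorded from the
tracheosyringeal nerve is cleaned, aligned to song, and tracked
longitudinally; stimulation-evoked compound responses are detected by
bootstrap and summarized as recruitment curves; and current-steering
stimulation specificity is quantified through fictive-vocalization
acoustics and spectrogram embeddings. This note records the models, the
parameter choices that matter, and the places where the design was
genuinely open.

## Synthetic data generator (`synthgen`)

The generator produces data with the statistical structure the analyses
assume, so every stage can be exercised end to end without animal
recordings. All generators are deterministic in (spec, seed).

**Song.** A bird is a list of syllable specifications plus a motif order.
Syllables are harmonic stacks with a time-varying fundamental
(0.35-3.8 kHz), vibrato (`fm_depth`, Hz at a fixed 35 Hz rate), sinusoidal
amplitude modulation (`am_rate`), raised-cosine 4 ms edges, and a shaped
broadband-noise admixture whose power fraction is `exp(entropy_level)` —
giving independent handles on each of the five acoustic features.
Rendition-to-rendition variability multiplies duration, pitch, AM rate and
gain by `1 + jitter * N(0,1)` (default jitter 2%, the stereotypy of
crystallized adult song). Audio is mono at 44,150 Hz; syllable onsets,
offsets and labels are returned as ground truth.

**Nerve recording.** Six channels at 30 kS/s (chronic default; the acute
rate is 24.4 kS/s). Each channel receives an independent
inhomogeneous-Poisson event train whose rate follows a per-motif envelope
template (peak 600 events/s per channel by default), convolved with a
biphasic ~0.35 ms spike kernel with log-normal amplitudes around 90 uV —
peak-to-peak motif voltages land in the hundreds-of-microvolts regime. All
channels share one band-limited (10-500 Hz) stochastic process scaled by a
per-channel gain: a rank-1 common-mode artifact, verifiable by SVD. The
off-nerve variant omits the neural term entirely and keeps artifact and
noise, mirroring a dummy device implanted next to the nerve. Independent
Gaussian noise (10 uV default) completes the model. Not emulated:
realistic EMG spectra, electrode drift, unit waveform diversity, or any
nerve biophysics — tests passing on this model demonstrate pipeline
correctness, not performance on real recordings.

**Evoked trials.** A peri-stimulus window from -5 to +25 ms at 24.4 kS/s
containing: a biphasic rectangular stimulation artifact in 0-0.5 ms scaled
by current; a compound response — a Gaussian-windowed oscillation confined
to the 0.75-4 ms latency span — whose peak-to-peak amplitude follows
`vmax / (1 + exp(-(I - i50)/slope))`; and Gaussian baseline noise. Onset
jitter is available for exercising trial alignment.

**Fictive vocalizations.** Stimulation patterns map onto a deterministic
factorial grid of syllable-parameter space (4 pitch x 3 AM-rate x
2 entropy x 2 sweep levels), with `mapping_spread` scaling the grid extent
(0 collapses every pattern onto one syllable). A random initial design was
rejected: independent draws let distinct patterns collide acoustically,
which contradicts the premise that each pattern drives a distinct
articulatory state. Fictive syllables span the full 200 ms analysis window
(the vocalization outlasts the 100 ms stimulation burst), so window-edge
effects do not dominate rendition variability.

## Song detection and segmentation (`songdetect`)

Detection reproduces the song-triggered acquisition rule: per-frame
(10 ms, 5 ms hop, Hann periodogram) power in the 2.5-8 kHz song band must
exceed `ratio_threshold` (default 20, configurable over the 10-50 range)
times the 50-250 Hz noise-band power; episodes are extended 1.5 s past
song offset and merged. The ratio form makes detection invariant to
waveform gain; silent input is handled by an energy floor rather than a
0/0.

Segmentation thresholds the rectified, 2 ms-boxcar-smoothed envelope
(default threshold 5% of the envelope peak — the level is not dictated by
the protocol and is exposed), drops runs under 10 ms and merges gaps under
5 ms. Annotation vectorizes each segment as a log-spectrogram resized to a
fixed 5,000-input grid and trains a small classifier (MLP with one
100-unit hidden layer by default; logistic regression available) over the
3-10 syllable classes, reporting held-out accuracy — the contract is label
assignment plus accuracy, not a specific architecture.

## Acoustic features (`acoustics`)

Five features per millisecond from 10 ms Hann windows, the standard
parameterization for zebra finch song: pitch (autocorrelation peak with
parabolic refinement, searched in 0.3-8 kHz, flagged unvoiced when the
normalized peak is < 0.35), frequency modulation (the angle
`atan2(|dS/dt|, |dS/df|)` of power-weighted log-spectrogram derivatives),
amplitude modulation (relative derivative of band power, 1/s), Wiener
entropy (log of geometric over arithmetic mean of the 0.3-8 kHz spectrum;
0 for white noise, strongly negative for tones), and envelope (total band
power, dB). Two numerical choices: the spectrum is lightly smoothed across
frequency (9-bin boxcar) before the entropy because single-periodogram
bins are exponentially distributed and bias the geometric mean downward by
~0.58 nats; and the spectral floor scales with each frame's maximum so
that all features are exactly invariant to waveform gain (the dB envelope
shifts by exactly `20 log10 g`). Edge rule: the segment is reflect-padded
so the track has one frame per millisecond of the segment; the first and
last ~10 ms are edge-contaminated, and analyses that need unbiased means
should trim symmetrically.

## Acoustic similarity (`similarity`)

Two vocal elements are compared millisecond-by-millisecond in the
5-dimensional feature space, features z-scored by the null's pooled
per-feature mean/SD (the units are incommensurate). The median Euclidean
distance is converted to a score by the empirical distribution of median
distances between unrelated songs (default 20 songs from distinct birds):
`score = fraction of null between-song medians >= observed median`. The
score is 1 exactly when the element is compared with an identical copy
(median 0, assuming a non-degenerate null — degenerate nulls trigger a
warning) and ~Uniform(0,1) for unrelated pairs, i.e. it is an empirical
P value.

Design choices:

* **Pairing.** Milliseconds are paired by index (the i-th of one rendition
  against the i-th of the other, truncated to the shorter track). The
  all-cross-pairs alternative is available (`pairing='cartesian'`,
  subsampled above 10^6 pairs) but cannot make the identical-copy score
  exactly 1, because off-diagonal self-pairs have nonzero distance; the
  aligned reading preserves the stated meaning of the scale endpoint.
* **Null contents.** The scoring ECDF uses one median distance per
  cross-bird rendition pair; the pooled per-ms distances (capped at 10^5)
  are retained on the null object alongside the fitted scaler.
* **Unvoiced frames.** Pairs with an unvoiced member drop the pitch
  dimension and rescale the 4-D distance by sqrt(5/4) rather than imputing
  a pitch.
* **Calibration domain.** Score uniformity holds for held-out renditions
  of the null's own bird population. For birds far outside that
  population the score remains a valid ordering but its P-value
  calibration degrades, because 20 songs only loosely pin the bird-pair
  median distribution — the same caveat applies to any empirical null of
  this size.

Group analyses: the nerve-function assay compares post-manipulation
syllables to baseline per label (up to 100 rendition pairs per type),
normalized to the pre-period split-half mean; stimulation specificity
averages pairwise scores within versus across pattern labels, excluding
and reporting single-trial labels.

## ENG preprocessing and alignment (`neuralproc`)

Common-mode subtraction removes the per-sample across-channel arithmetic
mean (exact for rank-1 artifacts up to gain differences; idempotent and
linear; order with respect to filtering is configurable and defaults to
CMS first). Filtering is a two-pole Butterworth band-pass (0.3-6 kHz)
applied forward-backward, hence zero-phase: a symmetric pulse's peak is
not displaced. Envelopes square the signal, smooth with a boxcar (5 ms for
analysis, 20 ms for display-style traces), average channels, and can be
decimated to 1 ms steps.

Motif alignment is dynamic time warping over log-spectrogram frames
(10 ms window, 1 ms hop), Euclidean frame distance, symmetric steps, and a
Sakoe-Chiba band of +-100 ms around the length-scaled diagonal. The
template is the medoid rendition (minimum summed DTW cost), searched over
a 16-rendition subsample when batches are larger — the full O(n^2) search
adds nothing but time. The warp transfers to simultaneously recorded
voltage or envelope traces through a piecewise-linear time map
interpolated from the frame-level path, resampling rather than
duplicating samples, with no premotor shift.

## Stability metrics (`stability`)

Per motif: Pearson correlation of the song-aligned envelope to the day-1
mean envelope (running version: sliding mean over 25 trials, advance 1;
zero-variance windows are flagged, not dropped); Vpp (max minus min of the
processed voltage in the motif window); SNR as `10 log10(RMS_S / RMS_N)` —
the literal RMS ratio, not a power ratio — against a 500 ms
vocalization-free segment from the post-song roll; and event rate, upward
crossings of mean + 5 SD of that motif's envelope divided by the unwarped
duration, with a one-smoothing-window refractory so a single burst is not
double-counted (the SD is taken on the smoothed envelope; configurable).

The day-1 reference mean includes day-1 trials, so with n trials per day
the day-1 correlation is inflated by O(1/n); daily trial counts of ~25
(the same scale as the running-window width) keep this negligible.
Day-level comparisons are two-tailed paired t-tests against day 1, with
Holm correction inside each metric's family of comparisons per the
multiple-comparison policy.

The on/off-nerve comparison pairs simultaneous trials, reports per-trial
SNRs and envelope correlations, and builds a 95% CI for zero correlation
by bootstrap over circular time-shifts of one member of each pair (10,000
resamples) — shifting preserves autocorrelation, which naive shuffling
would destroy.

## Evoked responses (`evoked`)

Trials are aligned on the stimulation artifact onset (first
first-difference exceeding 8 robust SDs of the pre-stimulus derivative;
artifact-free trials are excluded and reported). Response metrics use a
0.75-4 ms signal window and a 10.75-14 ms noise window; the default
aggregation is the mean trace over ~20 trials.

Detection is deliberately conservative about an under-specified rule: the
null distribution of the SNR statistic is built by resampling both
"signal" and "noise" windows (with replacement, 10,000 draws) from the
noise interval of the trial-mean trace; a response is detected when the
observed SNR exceeds the upper limit of the two-sided 90% CI of that null.
One-sided exceedance of a two-sided 90% CI gives a nominal 5%
false-positive rate, which the test suite verifies by Monte Carlo. The
alternative reading — a CI of the observed SNR under trial resampling,
detection when its lower limit clears 0 dB — is implemented behind
`mode='ci_of_observed'`.

Recruitment curves fit `Vpp(I) = baseline + vmax/(1 + exp(-(I-i50)/slope))`
by bounded least squares (slope > 0, vmax >= 0); non-convergence is
reported with diagnostics, never silently replaced. The threshold current
is operational — the smallest tested current whose trials pass detection —
rather than a sigmoid-derived quantile, and is reported as "beyond the
tested range" (None) when nothing is detected. Condition comparisons
normalize per-subject amplitudes to baseline, run a repeated-measures
ANOVA (sphericity checked; Huynh-Feldt-corrected p used when it fails)
and Dunnett contrasts against the control condition; these standard
procedures are delegated to established statistical routines.

`compression_force_limit` converts a compression pressure over a contact
area to force (133.322 Pa/mmHg): 30 mmHg over ~0.03 mm^2 gives the
~120 uN safety bound.

## Current steering (`steering`)

A pattern assigns each of the six electrodes (2 x 3 grid) a role —
cathodic-leading source, anodic-leading source, return, off — with
charge-balanced biphasic bursts (100 pulses, 1 kHz, 200 us/phase
defaults). Validation checks source/return presence, positivity, and the
constant-total-source-current constraint across a pattern set.

Vocalizations are vectorized as 200 ms from stimulation onset: 5 ms Hann
frames advancing 1 ms, 512-point transform, DC bin excluded and bins above
8 kHz discarded — bins 1-91 (86-7,847 Hz at 44.15 kHz), giving exactly
200 x 91 = 18,200 log-power values. The DC-excluded reading is the one
that yields 91 bins; including DC gives 93 and was rejected. Log
magnitudes are clamped at -60 dB: without a floor above the recording
noise, the thousands of silent bins fluctuate freely and dominate
Euclidean distances. Embedding is PCA to 50 components followed by 2-D
t-SNE (Euclidean, perplexity 35), initialized from the scaled PCA
projection with a recorded seed so coordinates reproduce bit-for-bit;
component count and perplexity shrink with a warning on small samples.

## Orchestration and reporting (`report`, `analysis/`)

`run_pipeline` executes the synthetic chain (synthesis -> detection ->
features -> similarity null -> nerve simulation -> preprocessing ->
stability metrics) in dependency order, validates configuration keys
before any computation, and writes metrics, logs (versions, seed, stage
durations) and the resolved config; identical (config, seed) runs produce
byte-identical outputs. `summarize` wraps paired/unpaired t-tests and the
repeated-measures ANOVA + Dunnett design with the conventional star
annotations (* < 0.05, ** < 0.01, *** < 0.001). The numbered scripts under
`analysis/` are thin narrative drivers over the library; they write their
tables under `results/`.

## Problem sizes

Tests and the analysis scripts run at deliberately desk-scale sizes chosen
to keep every Monte-Carlo check well-powered: similarity nulls from 20
songs x 3 renditions (1,710 between-song medians); 500 held-out pairs for
the uniformity check; 200 response-free datasets x 10,000 bootstrap draws
for detection calibration; recruitment at 8 currents x 20 trials;
stability over 3 birds x days {1, 10, 20, 30} x 25 motifs/day; steering at
24 patterns x 20 trials. These are the package's chosen study conditions,
not tuning knobs.

## Known limitations

* The generator's acoustic and neural variability is idealized; none of
  the validation here speaks to microphone artifacts, cage noise, EMG
  invasion spectra, electrode degradation, or real syllable diversity.
* Similarity-score calibration is tied to the null's bird population (see
  above).
* The DTW band assumes rendition-to-template tempo differences within
  +-100 ms; gross tempo changes need a wider band.
* The bootstrap detection null treats noise-window samples as
  exchangeable, which is accurate for white noise and approximate for
  strongly autocorrelated noise floors.
* `annotate_syllables` reports held-out accuracy on the training pool; it
  does not model annotation drift across days.
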