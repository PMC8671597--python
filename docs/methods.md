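# Methods

`pitchsim` implements a model-psychophysics pipeline for pitch perception:
synthetic stimuli are rendered through an auditory-nerve-like front end,
small convolutional networks are trained to classify the fundamental
frequency (F0) of short sounds, and the trained networks are run through
simulated versions of classic psychoacoustic experiments.  This note
documents the models, the parameters that matter, the numerical choices, and
what the package's synthetic conditions do and do not show about real data.

## Sound and level conventions

Waveforms are sound-pressure signals in pascals at 32 kHz.  Levels follow
the standard convention dB SPL = 20·log10(rms / 20 µPa); "level per
component" is the rms level of that partial alone.  Signal-to-noise ratios
are rms ratios; `mix_at_snr` rescales the noise and leaves the signal
untouched.  Setters invert exactly: set-then-measure agrees within 0.01 dB.

Psychophysical stimuli are synthesized as 150 ms signals — the 50 ms
analysis target flanked by 50 ms of continuation on each side — so the
periphery can excerpt the middle 50 ms and avoid onset/offset transients.
No onset ramps are applied (none are part of the stimulus definitions);
users who need them can window the samples.

## Stimulus families

* **Harmonic complexes** are sums of sinusoids with phase modes sine (0°),
  cosine (90°), random (i.i.d. uniform on [0, 2π)), and alternating (odd
  harmonics sine, even cosine).  Alternating phase doubles the envelope peak
  rate for unresolved harmonics — the basis of the pitch-doubling
  experiment.
* **Frequency-shifted complexes** use three F0-dependent spectral envelopes
  with a flat passband (3 harmonics wide centered on harmonic 5; 5 wide on
  11; 5 wide on 16) and flanking slopes of amplitude (10^x − 1)/9 with
  x = 1 − |(F − F_e)/(1.5·F0)| and zero for x ≤ 0.  Components sit at
  (n + shift/100)·F0, i.e., a common Hz offset expressed in %F0.
* **Mistuned-harmonic complexes**: 12 equal-amplitude sine-phase harmonics
  (60 dB SPL per component) with one component displaced proportionally.
* **Transposed tones**: a half-wave-rectified low-frequency sinusoid,
  lowpass filtered (4th-order Butterworth, cutoff 20% of the carrier
  frequency) and multiplied onto a high-frequency carrier, placing
  low-frequency temporal information at a high-frequency cochlear place.
* **Masking noises**: modified uniform masking noise with spectrum level
  15 dB/Hz SPL below 600 Hz rolling off at 2 dB/octave above; and
  threshold-equalizing noise realized as equal power per ERB (default
  10 dB SPL per ERB) on the Glasberg–Moore scale — the published recipe
  names the noise without a formula, so the equal-ERB-power reading is the
  package's own, documented here.  Both are Gaussian noises shaped in the
  frequency domain; measured spectrum levels agree with the target within
  ±1 dB when averaged over several seconds.
* **The translatable bandpass filter** (lowest-audible-harmonic
  experiments): the magnitude response of a 4th-order Butterworth bandpass
  (2500–3500 Hz at −3 dB) translated along the frequency axis so the lower
  −15 dB edge lands on a chosen frequency, applied as zero-phase magnitude
  multiplication in the frequency domain.  A causal filter cannot realize a
  translated response; the zero-phase form preserves exactly the passband
  placement the protocol needs.

## Surrogate auditory periphery

The front end is a deliberately simple surrogate for a biophysically
detailed auditory-nerve model.  It preserves the response properties the
experiments manipulate, and exposes a plug-in point (any object with
`render(waveform) -> Nervegram`) for a full nerve model.

Pipeline per fiber: 4th-order gammatone magnitude filter → half-wave
rectification → Butterworth lowpass (the inner-hair-cell membrane; default
7th order, 3000 Hz) → instantaneous compressive rate map → anti-aliased
resampling to the output rate → middle-50 ms excerpt.  Defaults give a
100-fiber × 1000-timestep nervegram at 20 kHz.

Key choices:

* **CF grid**: 100 fibers uniform on the ERB-number scale between 125 Hz
  and 14 kHz (`ERB(f) = 24.7(4.37 f/1000 + 1)`,
  `ERBn(f) = 21.4 log10(0.00437 f + 1)`); a linear mode spaces 100 fibers
  evenly over 125–8125 Hz with a fixed 80 Hz 10-dB bandwidth.
* **Filter shape**: the amplitude response is the symmetric 4th-order
  gammatone form |H| = [1 + ((f − cf)/b)²]^−2, applied zero-phase in the
  frequency domain (stimuli are short, so the whole segment is transformed
  at once).  For this prototype ERB = 0.9817·b (the classic 1.019·ERB
  factor) and the 10-dB bandwidth is 1.797·ERB, which fixes the
  80 Hz-bandwidth conversion in linear mode.  `bandwidth_scale` multiplies
  the ERB directly (0.5 = twice as sharp, 2.0 = twice as broad).
* **Phase-locking limit**: the IHC lowpass cutoff is the manipulated
  variable (50, 250/320, 1000, 3000, 6000, 9000 Hz; both 250 and 320 appear
  in the source literature's two listings, so both are accepted).
* **Rate map**: rate = spont + (250 − spont)·tanh(g·drive^0.3) with
  spont = 70 spikes/s by default (0.1 in the low-spontaneous variant); g is
  calibrated analytically so a 50 dB SPL tone at CF drives the fiber to half
  saturation.  Rates are non-negative by construction and silence maps to
  the spontaneous rate.  Because the map saturates, place cues (excitation
  pattern peaks) degrade at high levels — as they do for real high-spont
  fibers.
* **Tuning curves**: threshold at each probe frequency is the lowest level
  raising the mean rate 10% above spontaneous (77 spikes/s for a 70
  spikes/s fiber), interpolated on a level grid; the filter chain is linear
  up to the rate map, so the chain is run once per probe and rescaled per
  level.  Surrogate thresholds are meaningful as *shapes* (bandwidths,
  relative sensitivity), not as absolute dB SPL thresholds of any real
  fiber population.
* **Padding**: the 100 ms of continuation is split symmetrically around the
  50 ms target (the split is not dictated by the protocol; symmetric is the
  package's choice).

`flatten_excitation` removes place cues by scaling each fiber to the grand
mean rate (dividing each row by its time-averaged rate and multiplying by
the mean over rows); it conserves the grand mean exactly and is idempotent.
`transpose_layout` and `resample_channel_axis` support the
timing-manipulation controls that swap fiber/time axes at 2 kHz.

## Synthetic training corpora

Real speech/music corpora are replaced by a generator that reproduces their
statistical structure:

* **Label grid**: 700 log-spaced F0 bins from 80 to 1000 Hz, 1/16 semitone
  (0.36% F0) wide; bins are half-open geometric intervals and classes decode
  to geometric bin centers (center vs edge is not dictated; centers halve
  the worst-case quantization error, ≤ 0.18%).
* **Spectral envelopes**: a multivariate Gaussian over the first 13
  mel-frequency cepstral coefficients (40-band mel filterbank, 50 Hz–16 kHz,
  c0 excluded so overall level is carried separately), fitted to a family of
  envelopes and sampled per example; sampled envelopes are imposed on
  equal-amplitude cosine-phase harmonic complexes with harmonics up to
  16 kHz.  Anti-matched corpora negate the Gaussian mean (inverting the
  mean envelope) and keep the covariance.  Inverting 13 coefficients to an
  envelope and re-measuring them smooths through the filterbank, a small
  deterministic bias documented in the tests.
* **Profiles**: `speech_like` (steep lowpass tilt, formant-like resonances,
  large variance) and `music_like` (shallower tilt, smaller variance) are
  synthetic stand-ins for the corpus differences; they capture envelope tilt
  and variance only — none of the temporal or phonetic structure of real
  corpora.  Background noise is spectrally matched via the same cepstral
  machinery fitted to power spectra, and screened for periodicity
  (normalized autocorrelation ≤ 0.8 at all lags above 1 ms; the unbiased
  estimator over lags up to half the duration, so short segments are not
  penalized by the taper of the biased estimator).
* **Per-example draws**: SNR uniform (−10..+10 dB by default; +10..+30 and
  noiseless variants), overall level uniform 30..90 dB SPL, F0 log-uniform
  within its bin; exemplar counts per bin are met exactly and the dataset is
  bit-reproducible from its seed.  Filtered-corpus variants apply random
  Butterworth filters (order uniform 1–5; cutoffs log-uniform, lowpass
  500–5000 Hz, highpass 1–10 kHz) forward and backward.

The full-scale configuration (700 bins × 3000 exemplars = 2.1 M examples)
is representable and counted without being materialized; the desk-scale
default is 50 bins × 20 exemplars.

## F0-classifier networks

Architectures are sampled from the published search distribution: 1–8 conv
layers; first-layer kernel count 16/32/64 (p = 1/3 each), then ×2 (1/2),
×1 (1/3), ×1/2 (1/6) per layer within [16, 1024]; kernel frequency dims
uniform on 1..N_f/2 and time dims on N_t/20..N_t/2 with area capped at 256
by resampling; pooling strides uniform 1–4 (freq) and 1–8 (time); a
penultimate fully connected layer with probability 1/2 and width in
{128, 256, 512, 1024}.  Each conv block is Conv(valid, stride 1) → ReLU →
Hanning-window weighted average pooling → batch norm; dropout (rate 0.5)
precedes the final fully connected layer and — deliberately — stays active
during evaluation as well as training, so predictions are stochastic and may
be averaged over a configurable number of passes (default 1).

The pooling window extent is 1 where the stride is 1 and 4× the stride
otherwise, per dimension; the kernel is sum-normalized (so constant inputs
are preserved; the normalization is not dictated elsewhere) and implemented
exactly as one dense pooling matrix per axis, which also serves as the
anti-aliasing comparison against naive subsampling in the tests.

Everything is plain NumPy with hand-written backpropagation (verified
against numerical gradients), trained with Adam (batch 64, learning rate
1e-4 at full scale), an 80/20 train/validation split, validation every 5000
steps, early stopping once accuracy stops improving by at least 0.5
percentage points per evaluation (baseline: the previous evaluation; the
best-so-far alternative is a config switch), and an abort rule for networks
below 5% accuracy at 10,000 steps.  Running batch-norm moments are
zero-initialized and bias-corrected by 1 − momentum^n at evaluation, so
short desk-scale runs do not evaluate against the initialization.

The model surface is statsmodels-style: `F0Classifier` binds data, labels,
grid and architecture; `fit()` returns `F0ClassifierResults` carrying the
trained network, the evaluation trace, `summary()`, windowed prediction and
layer activations.

**Desk-scale defaults.**  The package's own reduced conditions, chosen once
so the full pipeline runs on a single CPU: 50 bins × 20 exemplars,
50-fiber × 250-timestep nervegrams (5 kHz output rate), a 2-conv-layer net
(16/16 kernels, penultimate FC 64), learning rate 1e-3, 800 steps, the
plateau rule disabled (the tiny validation split makes per-evaluation
accuracy too noisy for it), nervegrams standardized by the dataset mean and
standard deviation, and dropout-at-evaluation averaged over 2 passes.
Full-paper settings remain available behind the same configs.

A learnable cochlear front end is specified (100 one-dimensional 801-tap
kernels, valid convolution on 75 ms of 32 kHz audio so the output is 50 ms,
rectified and resampled to 20 kHz); the forward transform and the
best-frequency readout (argmax of the kernel's magnitude transfer function)
are implemented, training it end-to-end is not part of the desk-scale runs.

## Simulated psychophysics

All protocols operate on any estimator obeying the contract
`estimator(stimuli, window_centers, window_octaves, rng) -> Hz`, where
stimuli are lazy waveform recipes carrying the true F0.  Two estimator
families ship: network estimators (render → periphery → classifier →
windowed argmax; optionally with flattened excitation patterns) and a
Gaussian log-F0 oracle that perturbs the true F0 with noise of σ percent —
periphery-blind by construction, with the closed-form 2AFC threshold
√2·σ·Φ⁻¹(0.707) used to validate the harness end to end.

* 2AFC trials ask whether the higher-F0 stimulus of a pair received the
  higher prediction; ties are broken by seeded additive noise of magnitude
  1e-6 of the prediction range (or of the prediction magnitude when all
  predictions are equal).
* Psychometric functions group trials by their exact %-difference values
  (the stimulus grids are discrete, so no re-binning); pooling across
  reference F0s happens on proportions before fitting, because the ±6% log
  grids make the %-differences identical across references.
* Thresholds come from a least-squares location-scale cumulative-normal fit
  Φ((Δ − µ)/s); the 70.7% point is µ + s·Φ⁻¹(0.707), capped at 100%.
  Functions at ceiling return the smallest tested difference (flagged
  "floor"); functions at chance return the cap (flagged "cap").  The
  location-scale form makes the oracle's closed form exact (µ = 0,
  s = √2σ).
* Protocol grids (full scale): Experiment A — 2 phases × 30 lowest
  harmonics × 10 references (100–300 Hz log-spaced), 121 stimuli within ±6%
  of each reference, component level 48.3 dB SPL before filtering, masking
  noise added, window one octave: 7260 pairs per reference, 72,600 trials
  per threshold.  B — 3 fixed Butterworth passbands × 2 F0 ranges × 354
  alternating-phase stimuli, window 3 octaves, prediction/true ratio
  histograms in 2% multiplicative bins.  C — 3 envelopes × 7 shifts ×
  3917 F0s (80–480 Hz), 70 dB SPL, median shift per cell.  (The published
  total stimulus count does not match the product of the published grid; the
  F0 count is a parameter and the computed product is what the package
  reports.)  D — 3 nominal F0s × 7 shifts × 7 harmonics × 178 F0s within
  ±4%: 26,166 stimuli, mean shift per cell.  E — 6144 pure tones and 6144
  transposed tones per carrier (80–320 Hz), 5 reference frequencies, pairs
  among stimuli within ±1.35 semitones of a reference (the published
  per-threshold stimulus count of 684 is not derivable from the published
  grid; the half-window is a parameter and the 233,586-pair identity is
  exposed as C(684, 2)).  Correctness for transposed tones is defined by
  the envelope frequency.  Level experiment — 6144 pure tones 200–800 Hz,
  SNR +20 dB, levels 10–100 dB SPL in 10 dB steps, pairs within 2.7
  semitones pooled across frequency.
* Summaries: best threshold (value at lowest harmonic 1), transition point
  (first lowest-harmonic number with threshold > 1%), Cohen's d, and a
  probit transform of bounded similarity metrics ((r+1)/2 through Φ⁻¹;
  Fisher z available).
* Human-model similarity is a Pearson correlation between vectors built per
  experiment (log thresholds for A and E with interpolation across the
  stimulus axes and thresholds held constant below the 5th harmonic for A;
  re-binned histogram correlations averaged over conditions for B;
  interpolated shifts for C; 147 shifts with imputed zeros at the 12th
  harmonic for D).  Reference curves are user-supplied CSV;
  `data/human_reference_synthetic.csv` ships clearly-marked synthetic
  placeholders with the canonical qualitative shapes, because the published
  values are not redistributable.

## Network neurophysiology

Units are network activations after each conv layer's ReLU (plus the fully
connected layers); responses are time-averaged, binned on the 1/16-semitone
grid over 80–640 Hz, and unit-max-normalized over the full battery (5
compositions × 2304 F0s = 11,520 stimuli at full scale; components at
45 dB SPL in threshold-equalizing noise at 10 dB SPL per ERB).  F0 tuning
strength is the mean Pearson correlation between a unit's pure-tone curve
and each complex-tone curve.  Inharmonic controls jitter each harmonic above
the fundamental by a fixed pattern drawn uniformly on ±50% of F0, rejection
sampled so adjacent components stay ≥ 30 Hz apart at the enforcement F0
(80 Hz, the minimum tested, so the constraint holds for every stimulus);
analyses average over 5 jitter seeds.  The population response versus lowest
harmonic number (1–15, 9-harmonic complexes) reads each final-layer unit's
response at its best F0 and averages over all units of the final layer.

## What the synthetic conditions show — and don't

Passing tests demonstrate that the pipeline's machinery is correct: exact
protocol counts, exact level/SNR algebra, closed-form oracle threshold
recovery through the full experiment harness, periphery invariants, and a
desk-scale network that learns F0 classification far better than chance and
produces finite thresholds in the full Experiment-A loop.  They do not
demonstrate the headline behavioral phenomena of the full-scale system
(human-like threshold transitions, phase effects, pitch-shift magnitudes):
those require training hundreds of networks on millions of natural-sound
examples, far beyond a single-CPU run, and the synthetic corpora carry only
the coarse spectral statistics of natural sounds.

## Known limitations

* The periphery is a surrogate: no middle ear, no level-dependent tuning,
  no synaptic adaptation, no spiking; absolute thresholds are not
  comparable to a real nerve model's.
* Zero-phase filterbank processing discards cochlear latency/phase
  structure; experiments relying on cross-channel phase would need a causal
  front end through the adapter.
* The cepstral-Gaussian corpus stand-ins have no temporal fine structure or
  prosody; speech/music differences reduce to envelope statistics.
* Desk-scale networks are small and trained briefly; their psychophysics is
  expected to be coarse (thresholds near the quantization floor for easy
  conditions and at the cap for hard ones).
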