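# Methods

`errpfusion` re-implements, over a synthetic data source, a multimodal
analysis of error processing during a simulated VR glider flight: when the
interface misbehaves (the target ring jumps, or the glider rotates on its
own), the brain produces a stereotyped error-related potential (ErrP), the
pupil dilates, and the heart rate transiently decelerates — an orienting
response. The package decodes which of three error types occurred (or none)
from short windows of EEG and pupil data, and tests whether adding the pupil
channel helps EEG decoders with few electrodes.

No public recording of such a cohort is available, so the synthetic
generator is the canonical data source: it emulates the paradigm's event
structure and the error-related physiological responses with enough fidelity
that every preprocessing and decoding stage can be validated against
injected ground truth.

## The paradigm generator

One flight run contains 70 targets roughly 4 s apart (intervals jittered
±0.2 s). 30% of targets trigger an error — seven *target* jumps (exactly
1.6 s before the projected pass), seven *passive* and seven *active*
rotations (uniformly 1.1–1.8 s before the pass) — leaving 49 *correct*
targets per run. A session concatenates `n_runs` runs (default 9, the emulated session
length) on one clock with 5 s gaps.

**EEG** (63 named 10-5 channels, 512 Hz, µV) is built additively:

* *Event-locked components.* Gaussian bumps parameterized by (latency,
  amplitude, width) with Gaussian scalp maps centered on FCz (P1, ERN) or
  Cz (Pe, N400). Latencies encode the emulated grand-average responses — ERN at
  234/250/266 ms and Pe at 313/344/391 ms for target/passive/active, P1 at
  188 ms, N400 at 469/484/500 ms — so active-condition components are
  delayed per component, not by a global shift. Correct trials carry no
  event-locked components. Bump widths (16–45 ms), N400 amplitudes, and the
  ERN kernel amplitudes are generator choices: the target trough depths
  (−0.40/−0.27/−0.33 µV) are features of the *summed* waveform, so the ERN
  kernel is deeper (−2.0/−1.6/−1.7 µV) in order for the band-passed sum of
  P1 + ERN + Pe to actually exhibit a trough at the intended latencies.
* *Background.* Per-channel 1/f noise, default SD 4 µV broadband. With this
  level the ±35 µV/kurtosis/joint-probability rejection removes ~10% of
  trials — a realistic retention rate for seated VR recordings.
* *Ocular contamination.* Linear mixing of three sources — horizontal and
  vertical gaze angle and a smoothed blink waveform (blink indicator
  convolved with a 150 ms Hann kernel) — through fixed spatial gain maps
  (lateral-frontal antisymmetric for horizontal gaze, frontal for vertical
  gaze and blinks). The generator and the removal stage share the blink
  waveform definition, which makes the least-squares subtraction exactly
  verifiable.

**Gaze/pupil** (120 Hz): gaze wanders smoothly (low-passed noise, SD 8°/4°
horizontal/vertical); the observed per-eye pupil is
baseline (3.5 mm) + per-condition dilation bump + slow drift (< 0.05 Hz)
+ hippus-like in-band oscillation (0.2–0.6 Hz, SD 0.035 mm) + white
measurement noise (SD 0.01 mm) + a cubic function of horizontal gaze angle
(the pupil-foreshortening distortion, per-eye coefficient sets). Dilation
peaks at 625/656/734 ms for target/passive/active with amplitudes
0.12/0.10/0.09 mm, jittered per trial by a lognormal gain (σ = 0.3) —
evoked pupil responses vary far more across trials than across conditions.
Blinks (Poisson, 0.12 Hz, 200 ms) blank both eyes and set validity flags.

**RR intervals**: RR(t) = 0.8 s + RSA + post-error lengthening + jitter.
The respiratory sinus arrhythmia term (amplitude 0.04 s) uses a 0.31 Hz
default frequency with a random initial phase: breathing free-runs, and a
period commensurate with the 4 s target spacing would otherwise phase-lock
respiration to the trials — an artifact no real session has. The
deceleration kernel (2 bpm, minimum at 1.1 s, SD 0.3 s, converted to RR
units) is evaluated at the projected end of each interval, since an RR
interval reflects lengthening over its span.

**Eye-calibration runs** contain three labeled phases that partition the
recording — horizontal saccades stepping through seven angles (±30°),
vertical saccades, paced blinks — with the same ocular mixing and pupil
distortion as flight runs. Two calibrations per participant mirror the
two-block protocol.

**Cohorts** share the condition structure (latencies are paradigm truth)
and differ in noise seeds and an overall response-gain factor (lognormal,
σ = 0.15).

### What the generator does *not* emulate

Real EEG's spatial covariance (a forward head model), non-stationary
artifacts (muscle, electrode drift), saccadic spike potentials, true
breathing dynamics, and — importantly — the realistic ceiling of pupil
informativeness: the synthetic single-trial pupil SNR is optimistic, so
pupil-only decoding accuracies on synthetic cohorts sit well above the
barely-above-chance regime seen with real recordings. Passing tests therefore
demonstrate correctness of the pipeline's operations and the direction of
the fusion effects, not expected real-data performance levels.

## Preprocessing

*EEG*: zero-phase Butterworth band-pass 0.4–30 Hz (order 4) with 50/100 Hz
notches → ocular subtraction (below) → zero-phase 1–10 Hz band-pass →
anti-aliased resampling to 64 Hz → removal of Fp1/Fp2/AF3/AFz/AF4 (58
channels remain) → epoching ([−0.5, 1] s around error onset; correct trials
[1.5, 3] s after the previous target pass) → trial rejection → bad-channel
interpolation. No explicit EEG baseline subtraction: the 1 Hz high-pass
serves that role.

*Ocular subtraction* regresses each channel onto the three references
(gaze angles and the blink waveform rebuilt from validity flags), fitted by
least squares on the labeled artifact segments of the calibration runs
only, and applied block-wise (calibration 1 → runs 1–4, calibration 2 →
the rest). When applied to filtered EEG the references are passed through
the same filters, so linear contamination cancels exactly. This is a
generic multi-reference subtraction, deliberately matched to the
generator's linear mixing so recovery is provable.

*Trial rejection*: a trial goes if any sample exceeds ±35 µV, or any
channel's kurtosis or joint-probability statistic (mean negative log of a
kernel-density amplitude estimate over pooled trials, subsampled to 5000
points per channel and evaluated on a 512-point grid) z-scored across
trials exceeds 5 SD. Both statistics are computed per channel per trial —
the most conservative reading of a per-statistic 5 SD rule. Channels whose
pooled variance exceeds Q3 + 1.5·IQR are rebuilt by spherical-spline
interpolation on the template montage positions; more than 25% flagged
channels aborts. Visual-inspection steps common in manual workflows are
replaced by these automated rules (a user-supplied exclusion list can be
passed instead of the variance flags).

*Pupil*: linear blink interpolation per eye (validity flags kept for
audit) → resampling to 128 Hz + zero-phase 0.1–10 Hz band-pass → cubic
foreshortening correction → eye averaging → epoching with variance-IQR
rejection run separately for error and correct pools → baselines (error:
mean of [−0.5, 0] s; correct: whole-trial mean). The foreshortening model
is a per-eye least-squares cubic of pupil size on horizontal gaze angle
over the horizontal-saccade calibration segments; only the gaze-dependent
part (relative to the cubic's value at the mean calibration angle) is
subtracted, preserving absolute level; subtracting the full cubic
including its intercept would be equivalent downstream, since trial
baselines remove absolute level anyway. Vertical gaze is not in the model (the observed
dependency is horizontal).

*Cardiac*: beat-wise HR = 60/RR at each R peak, linear interpolation to a
uniform 4 Hz grid (a documented default; HR dynamics of interest are
≪ 1 Hz), [−0.5, 3] s epochs,
baseline-corrected by the pre-onset mean. The deceleration metric is the
minimum of the per-condition trial average in [0.7, 1.7] s. Beat-rate
sampling plus linear interpolation attenuates a 0.3 s-wide dip by roughly a
third to a half — the module's recovery tests budget for exactly this loss.

## Decoding

Epochs are resampled to 32 Hz (48 samples). A window of 1/4/8/16 samples
(1 sample to 500 ms) slides in 1-sample steps — an output every 31.25 ms —
and an output at time *t* uses the window *ending* at *t*, so information
appears in the trace only after it has entered the window. Features are the
raw amplitudes of the layout channels in the window (C·W values; layouts:
FCz; FCz/Cz/Pz; all 58), z-scored per feature on the training folds,
projected onto the principal components explaining 99% of training
variance, and classified by a four-class LDA with analytic Ledoit–Wolf
covariance shrinkage (the standard parameter-free choice behind
"shrinkage LDA"). Classes are
balanced first (all error trials; correct subsampled to the rounded mean
error-class count, round-half-to-even) and evaluated with 10×5 stratified
cross-validation (stratified: it stabilizes small per-class counts). Fold accuracies are averaged unweighted. Ties in the
decision scores break toward the lowest class index.

*Simple fusion* appends the 32 Hz pupil trace as one extra channel on the
trials surviving both modality rejections; the per-feature standardization
delivers the zero-mean/equal-variance contract between modalities.
*Bayesian fusion* trains both unimodal classifiers on the same folds,
estimates each classifier's confusion matrix from its own training-fold
predictions (optimistically biased; see limitations), adds
Laplace +1 smoothing, column-normalizes into P(true | predicted), and
multiplies the two conditionals with uniform priors (classes are balanced);
the fused class is the argmax. Smoothing is our addition: training-fold
confusions can have empty columns, and +1 prevents zero beliefs.
*Generic (transfer) decoding* replaces the CV with leave-one-participant-out:
train on everyone else's balanced pool, test on the held-out participant.

## Statistics

The chance-level threshold for n trials and c = 4 classes is the smallest
k/n with the upper-tail cumulative binomial probability
P(X ≥ k) = Σᵢ₌ₖⁿ C(n,i)(1/c)ⁱ((c−1)/c)ⁿ⁻ⁱ ≤ α = 0.05, averaged over
per-participant trial counts. (A form that sometimes circulates writes the complement exponent as n−1, which does not yield a probability distribution; the standard cumulative form above is the one that reproduces the 25% chance level and the ~30% threshold regime.) Wilcoxon signed-rank tests
(exact null up to n = 25, normal approximation beyond; all-zero difference
vectors return p = 1) with Benjamini–Hochberg FDR compare peak pupil
dilations ([0.5, 0.8] s) and HR decelerations ([0.7, 1.7] s) against
correct-trial extrema, and accuracy traces sample-wise between methods.
Friedman tests compare the three decoder families per window length on peak
accuracy and mean correct fraction over [0, 1] s, with Nemenyi post-hoc
comparisons (studentized-range null on mean rank differences) only where
the omnibus test is significant; with exactly two methods the omnibus
reduces to the paired signed-rank test.

## Numerical and design notes

* All filters are applied forward–backward (zero phase); latency claims
  rely on this.
* The session clock is seconds with t = 0 at stream start; consumers
  convert to their own sample indices, so modality rates never couple.
* Kernel placement snaps to the EEG sample grid (≤ 1 ms); recovery tests
  use one-sample tolerances at the relevant analysis rate.
* Deterministic given seeds: every stochastic step derives its generator
  from a master seed (participant p gets `master·1000 + p`; streams within
  a participant use fixed sub-keys), and the gaze/blink processes are
  derived identically in the EEG and pupil paths so ocular references
  match across modalities.
* Problem sizes in the analysis scripts and the acceptance script are
  scaled (6–10 participants, 2–3 runs, 2–3 CV repetitions) as the
  package's working defaults for a single desk CPU; latency-type results
  are set by injected component timing and are insensitive to this
  scaling, while accuracy-type results on synthetic cohorts are reported
  as regimes, not point reproductions.

## Known limitations

* The EEG has no forward-model spatial structure, so spatial-filter-heavy
  methods would look better here than on real data.
* Confusion matrices from training-fold predictions are optimistic; an
  inner-CV estimator would be less biased (the training-fold estimator is
  what the protocol prescribes, so it is the default).
* The binomial threshold treats evaluation-time outputs as independent
  trials, which overstates the effective trial count for overlapping
  windows.
* Pupil decoding accuracy on synthetic data exceeds the real-data regime
  (see the generator's non-goals above).
* No gamma-band/time–frequency features, no respiration removal from the
  RR series, and no cardiac classification — all outside this analysis.
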