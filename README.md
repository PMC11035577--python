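# errpfusion

Multimodal decoding of error processing in a simulated VR flight task:
EEG + pupillometry + cardiac preprocessing, asynchronous sliding-window
multiclass classification of three error types versus correct behaviour,
and hybrid EEG+pupil fusion — exercised end-to-end on a synthetic-data
generator that emulates the paradigm and its physiological responses.

## The problem

In an immersive flight simulation, a participant steers a glider through
rings. Occasionally the interface errs: the next ring jumps sideways
(*target* error), or the glider rotates on its own while the participant is
passive or actively steering (*passive* / *active* interaction errors).
Perceived errors elicit an error-related potential (ErrP) over frontocentral
cortex — an early positivity (P1, ~188 ms), the error-related negativity
(ERN, ~234 ms for target errors), the error positivity (Pe, ~313 ms), and a
late negativity (N400) — followed by a slower pupil dilation (peaking
~625 ms) and a transient heart-rate deceleration: the orienting response.

A brain–computer interface that detects such errors could let the system
undo or adapt its behaviour. Practical headsets have few EEG electrodes but
free access to eye tracking, which motivates the central question here: can
the pupil trace *decode* errors on its own, and does appending it to a
reduced EEG montage recover part of the accuracy lost by dropping
electrodes?

## The method

Per participant, cleaned epochs (EEG: 0.4–30 Hz + notches, calibration-based
ocular subtraction, 1–10 Hz, 64 Hz, 58 channels, ±35 µV / kurtosis /
joint-probability rejection, spherical-spline channel repair; pupil: blink
interpolation, 128 Hz, 0.1–10 Hz, cubic gaze-angle foreshortening
correction, variance rejection, baselines) are classified at 32 Hz by a
window sliding in 31.25 ms steps: features are the C·W window amplitudes of
a channel layout (FCz; FCz/Cz/Pz; or all 58), z-scored, projected onto the
principal components keeping 99% of training variance, and fed to a
four-class shrinkage LDA (Ledoit–Wolf), under 10×5 stratified
cross-validation with class balancing.

Two hybrid schemes combine EEG and pupil: **simple fusion** (SF) appends
the pupil trace as an extra data channel; **Bayesian fusion** (BF) fuses
the two unimodal predictions e₁, e₂ through training-fold confusion
matrices C_k = (n_ij):

    O(c_i) ∝ P(c_i) · ∏_k P(c_i | e_k = c_j),
    P(c_i | e_k = c_j) = n_ij / Σ_i n_ij,

with uniform priors and +1 smoothing; the fused class maximizes O.
Decoders are judged against the exact cumulative-binomial chance threshold
(smallest k/n with P(X ≥ k) ≤ 0.05 under guessing at 1/4), and group
comparisons use Wilcoxon signed-rank tests with Benjamini–Hochberg FDR and
Friedman/Nemenyi tests.

Because real recordings of this paradigm are not publicly available, the
package ships a
first-class synthetic generator (`errpfusion.synth`) that reproduces the
event schedule (70 targets/run, 7+7+7 errors, 49 correct) and injects the
response components at their reference latencies — making every stage testable
against ground truth. See `docs/methods.md` for the full model and its
limitations.

## Worked example

```python
from errpfusion import synth, eeg, pupil, decoding, fusion

cfg = synth.GeneratorConfig(seed=2, n_runs=3)
part = synth.simulate_participant(cfg)

es = eeg.preprocess_eeg(part)            # 58-ch epochs at 64 Hz
ps = pupil.preprocess_pupil(part)        # eye-averaged epochs at 128 Hz

ga = eeg.grand_average_erp([es])
print("ERN latency:", eeg.negative_peak_latency(ga, "FCz", "target"))

e_al, p_al = fusion.align_trials(es, ps.as_epochset())
bal = decoding.balance_classes(e_al, seed=11)
plan = decoding.make_folds(bal.labels, seed=29, repetitions=2)
res = decoding.decode_sliding(decoding.resample_epochs(bal), ["FCz"], 8, plan)
print("peak accuracy:", round(res.peak_accuracy, 3),
      "at", res.peak_time_s, "s")
```

prints (seed 2):

```
ERN latency: 0.234375
peak accuracy: 0.492 at 0.4375 s
```

i.e. the grand-average error negativity for target errors falls at 234 ms
(one 64 Hz sample grid point), and a single-channel FCz decoder with a
250 ms window peaks near 49% accuracy — roughly twice the 25% chance level
for four balanced classes — about 440 ms after error onset.

The numbered scripts under `analysis/` run the full narrative (schedule
checks, grand-average responses, the layout × window × fusion decoding
grid with report, pupil transfer decoding, response statistics), writing
tables under `results/`. The same machinery is scriptable via the
`errpfusion` CLI (`simulate` / `preprocess` / `decode` / `stats` /
`report` / `all`).

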