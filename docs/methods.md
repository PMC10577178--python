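# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `eegaug`, in the order the pipeline runs.

## Synthetic cohorts

Each subject's recording is filtered Gaussian noise shaped in the frequency
domain. The target one-sided PSD on the rfft grid is

```
S_g(f) = off_g(band(f)) · max(f, 0.5)^(−γ_g)
         + A_α,g · exp(−(f − c_α)² / 2σ_α²)
         + A_δ,g · exp(−(f − c_δ)² / 2σ_δ²)
```

per group g ∈ {HC, MDD}: a 1/f-type background (power ∝ f^(−γ), pole clamped
at 0.5 Hz, DC zeroed), multiplied inside each clinical band by a per-group
offset, plus Gaussian bumps at the delta and alpha centers. The signal is
`irfft(√S · z)` with z complex white Gaussian, so the expected periodogram
equals S up to a constant — which is what the frequency-domain evaluation
measures. Shaping in the spectrum was chosen over time-domain AR filtering
precisely because it gives direct, parameter-by-parameter control of the
quantity the analyses read out.

Defaults (per group unless noted): γ = 1.2; alpha peak (10 Hz, 1.5 Hz,
amplitude 0.3 in units of the 1 Hz background power); delta bump (1.5 Hz,
0.8 Hz, 0.6); band offsets HC = {δ 1.0, θ 0.55, α 1.0, β 1.0} and MDD =
{δ 1.35, θ 0.75, α 1.0, β 1.0}. The sub-unity theta offsets carve the theta
dip between the delta and alpha peaks that eyes-closed resting spectra show;
the elevated MDD delta/theta offsets encode the kind of low-frequency
diagnosis effect reported for real MDD cohorts. Cohort defaults are 24+24
subjects, 250 Hz, 300 s — the scale of the larger public MDD datasets.

**Inter-channel structure.** Every channel is `√ρ·s + √(1−ρ)·e_c` with a
shared source s and independent noise e_c drawn from the same spectrum, so
each channel keeps the target PSD and every channel pair has expected
correlation ρ (default 0.6). A single shared source is deliberately the
simplest structure that makes average re-referencing non-trivial.

**Between-subject variability.** Each subject multiplies the peak
amplitudes and band offsets by independent log-normal factors
(σ = `subject_variability`, default 0.5) and jitters the exponent by
N(0, (0.2σ)²). Resting-state band power varies across individuals with a
coefficient of variation of 50% or more, and without this term every
between-subjects test on the cohort would be degenerate: the subject is the
analysis unit of the ANOVA and of cross-validation. The default is a
realism choice, not a fitted value.

**Spike artifacts.** Poisson-timed 40 ms Hann-windowed transients on a
random channel, scaled to `magnitude` × that channel's standard deviation.
They exist to exercise the outlier-window filter; eye blinks, EMG and line
noise are intentionally not modeled.

**Determinism.** Every operation is a pure function of (spec, seed);
per-subject seeds derive from the cohort seed through `SeedSequence`.

## Preprocessing

The chain per recording: montage selection → average reference → band-pass
→ pluggable artifact stage (default: identity) → per-subject/channel
z-scaling → 8 s windowing → outlier rejection → joint [−1, 1] rescaling;
then balanced subsampling across the cohort (subjects to the smaller group,
windows to the smallest per-subject count).

* **Montage** — fixed 13-channel order Fp1, F3, C3, P3, O1, F7, Fz, Fp2,
  F4, C4, P4, O2, F8 (left hemisphere, midline, right hemisphere); matching
  is case-insensitive with a small alias table (T3→T7 style renames).
* **Band-pass** — order-5 Butterworth, forward-backward (`sosfiltfilt`),
  zero phase. The order is the smallest that meets the contract asserted in
  the tests: ≤3 dB loss at 10 Hz, ≥20 dB attenuation at 50 Hz for the
  1-40 Hz band at 250 Hz, and ≥20 dB one octave outside the edges.
* **Windows** — non-overlapping. Overlap would inflate the per-subject
  frame counts beyond the 5-minute arithmetic the design tables assume
  (300 s / 8 s → ≤37 windows, of which 16-18 survive cleaning).
* **Outlier rule** — per subject: with m_i/M_i the min/max over all entries
  of frame i, frame i is dropped iff `m_i < mean(m) − 2·std(m)` or
  `M_i > mean(M) + 2·std(M)` (population std; degenerate spread flags
  nothing). Statistics are computed per subject, with min/max taken jointly
  over channels — a deliberate reading of an ambiguous rule, documented
  here and frozen by an oracle test that recomputes it by brute force. The
  rule is a minority-outlier detector: when most windows of a subject carry
  spikes, the threshold adapts upward and nothing is flagged, which the
  tests exercise with sparse (0.5/min) spike rates.
* **[−1, 1] scaling** — joint over channels within a frame, not per
  channel, preserving inter-channel amplitude relations that are clinically
  meaningful; every frame attains both bounds exactly.
* **Artifact stage** — ICA-based artifact classification needs a pretrained
  component classifier and real electrode physics; the stage is therefore a
  plug-in callable whose default is the identity. The spike filter plus the
  band-pass cover everything the synthetic cohorts contain.

## Noise baseline

Uniform noise in ±`amplitude` (default 0.1 = 10% of the normalized range)
added i.i.d. per channel and sample, followed by re-applying the joint
[−1, 1] rescaling. Amplitude 0 returns the input unchanged. At band-power
granularity the operation is near-neutral: the acceptance suite verifies
that the data-type main effect of a real-vs-noise two-way ANOVA stays at
the nominal false-positive rate across seeded replicate cohorts.

## Conditional Wasserstein GAN

Generator: latent N(0, I₁₀₀) concatenated with a one-hot class label →
dense → reshape to (filters, channels, T/16) → four upsampling stages
(zero-interleave the time axis ×2, then a 'same' convolution — the adjoint
of a stride-2 convolution), LeakyReLU (slope 0.2) and batch normalization
between stages → one same-size convolution → tanh. Output values lie in
(−1, 1) like the real frames.

Critic: the frame plus a constant label plane (−1 for HC, +1 for MDD) →
convolutions with strides (2,2), (2,2), (1,2), LeakyReLU between → dropout
(0.25) → linear dense score. A Gaussian noise layer (σ = 0.05 of the
normalized range) perturbs the frame in training mode only, so a critic
facing a small dataset cannot simply memorize it. The symmetric ±1 label
encoding matters: with a 0/1 plane the HC condition carries no signal at
all into the convolution stack.

Training: Wasserstein losses (`mean(fake) − mean(real)` for the critic,
`−mean(fake)` for the generator), five critic minibatch steps per generator
step, weight clipping after every critic step, Adam with lr 5e-4, β₁ = 0,
β₂ = 0.999, ε = 1e-7 for both networks. Real and fake minibatches pass
through the critic as one concatenated batch so a single backward pass
serves both terms. The stopping rule is a fixed iteration budget; loss
histories are exported for stability inspection (their lengths are the 5:1
accounting invariant).

**Clip bound.** The default `clip_value` is 0.01, the conventional bound
for weight-clipped Wasserstein training. The bound interacts with network
width: in the scaled-down configurations used for testing (8-32 filters),
0.01 saturates the critic's label pathway — its score becomes numerically
independent of the label and conditioning cannot be learned — so the
conditional-recovery experiments run with 0.05. Both values are
config-exposed.

**Architecture defaults.** Kernel (3, 5), base_filters 16, critic filters
(16, 32, 64). The constraints that are fixed — latent size, stage counts,
strides, activations, tanh/linear outputs — are the contract; kernel and
filter counts are free parameters and deliberately configurable.

## Diagnosis classifier

Five blocks of convolution (stride 1, 'same'), ReLU, max-pooling and batch
normalization, then two hidden dense layers and a sigmoid output; binary
cross-entropy; Adam with lr 5e-4, β₁ = 0.9, β₂ = 0.999, ε = 1e-7; MDD is
the positive class. Pooling halves a dimension only while its extent is
≥2, so five blocks fit both the (13, 2000) and smaller test inputs without
collapsing. Epochs/batch default to 50/32 with no early stopping; accuracy
is frame-level, with per-subject majority aggregation available but off by
default. Precision is reported as 0.0 when no frame is predicted positive.

## Evaluation design

* **Cross-validation** — leave-two-subjects-out: each fold tests one HC and
  one MDD subject (all their frames) and trains on everyone else. Pairing
  is by sorted subject id, so the plan is deterministic. The subject-wise
  integrity invariant — no test-subject frame in any training material of
  its fold, through any augmentation source — is asserted inside
  `run_experiment` on every fold × condition.
* **Conditions** — REAL_100, AUG_100_ONLY, REAL_50_AUG_50 (half the real
  frames, group-stratified, plus an equal count of augmented frames),
  REAL_100_AUG_100, REAL_100_AUG_200. Counts are exact for arbitrary
  balanced cohorts; augmented frames are drawn seeded, without replacement,
  with the same group composition as the real frames they complement. The
  half condition is realized as half of the training frames stratified by
  group (rather than half of the subjects), which keeps the count exact for
  odd subject counts; both readings give the same totals.
* **GAN per fold** — retraining the generator inside every fold on that
  fold's training subjects is the default, because a generator trained on
  all subjects leaks the test subjects into the augmented frames. A
  train-once mode exists for speed and emits an explicit leakage warning.
* **Spectra** — plain periodograms (boxcar, no detrending), channel-
  averaged per frame; per subject, the mean across that subject's windows
  is the individual estimate. Band power is the *mean* power over the bins
  in [low, high). The delta band starts at 0.3 Hz although the band-pass
  starts at 1 Hz; both are kept as printed conventions, the delta bins
  below 1 Hz simply carry the filter's rolled-off power.
* **Synthetic analysis units** — generated data has no subjects, so
  sampled frames are matched in number to the real subjects per group and
  each frame enters the ANOVA as one unit.
* **ANOVA** — fixed-effects two-way (data type × diagnosis) with
  interaction on a balanced table, fitted via OLS (statsmodels, type-II
  sums of squares, equivalent to type-I/III under balance); F carries
  (1, N−4) degrees of freedom. The test suite re-derives the decomposition
  from first principles and requires agreement to 1e-8. Note that pairing
  real windows with their own noise-augmented copies makes the *diagnosis*
  effect anti-conservative (the two data-type levels are then near
  duplicates, halving the effective unit count); the parameter-recovery
  simulations therefore draw an independent cohort per data type.
* **t-tests** — one-sided, α = 0.05, uncorrected: pooled-variance
  two-sample between training conditions (df = n_a + n_b − 2) and
  one-sample against chance 0.5 (df = n − 1). These variants reproduce the
  degrees-of-freedom pattern of the study design (df 46 for 24 folds per
  condition; df 27 for 28 folds). Zero-variance samples degenerate to
  t = 0, p = 0.5 when the means agree.
* **Summaries** — mean ± t-based 95% confidence intervals.

## The neural-network core

No deep-learning framework is a dependency; the GAN and CNN run on a small
numpy layer library with hand-derived backward passes. Convolutions
decompose into one small GEMM per kernel offset over strided slices of the
padded input ('same' padding, asymmetric where needed); the input gradient
accumulates the transposed products back into the padded grid, avoiding
scatter-add indexing. All activations are float32. Every layer's gradient
is verified against central differences in the test suite. Batch
normalization keeps running statistics (momentum 0.9) for inference;
dropout and the Gaussian noise layer are identity at inference, making all
sampling and prediction deterministic given parameters.

## Scale of the tested experiments

The test and acceptance runs use scaled-down study conditions chosen to
keep the full suite around ten minutes of single-core CPU: cohorts of 5-12
subjects per group, 32-128 Hz sampling, 64-320 s recordings, 4-8 channels,
4-8 s windows; GAN runs of 200 generator iterations (fidelity) and 600
(conditional recovery) on 4 × 256 frames with 8-32 filters; classifiers
with 4-16 filters and 15 epochs. The full-scale geometry — (13, 2000) and
(13, 2048) frames, 24-fold plans, the five training-condition counts — is
exercised structurally (construction, shape, accounting) rather than
trained at full scale.

## What passing tests do and do not show

The synthetic cohorts have Gaussian marginals, stationary spectra,
linear channel mixing and parameter-level group differences. Real EEG is
non-stationary and non-Gaussian, with artifacts (ocular, muscular, line
noise) whose structure the generator does not attempt, and real MDD/HC
differences are far subtler than the injected offsets. Green tests
therefore certify the *machinery* — preprocessing contracts, leakage-free
cross-validation, exact condition accounting, statistical calibration,
GAN training mechanics and conditional controllability on separable
spectra — not clinical-grade performance of the GAN or classifier on
hospital data. Weight-clipped conditional training also retains a genuine
failure mode of the method: for some initializations it collapses toward
one class's spectrum, which is why the conditional experiments are judged
across seeds rather than on a single run.

## Known limitations

* No gradient penalty, progressive growing, or GPT/VAE baselines.
* No ICA/ICLabel stage (pluggable no-op instead); no topographic maps or
  2D embeddings; no figure rendering beyond CSV/plot-data export.
* No resampling between the 250/256 Hz design variants; cohorts are
  processed independently.
* The numpy core is single-threaded GEMM-bound; it is sized for the desk-
  scale experiments here, not for full-scale GAN training.
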