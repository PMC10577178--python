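# eegaug

Synthetic EEG cohort simulation, conditional Wasserstein-GAN data
augmentation, and CNN-based diagnosis evaluation for small two-group
clinical EEG studies (major depressive disorder vs healthy controls).

## The problem

EEG-based machine-learning diagnosis of MDD is limited by tiny cohorts: a
typical public dataset holds 20-30 subjects per group, each contributing a
5-minute eyes-closed resting-state recording. One remedy is to enlarge the
training set with artificial data — either a trivial baseline (adding
uniform noise to the real windows) or samples from a conditional generative
model trained to produce class-labeled EEG time-series. Whether that helps
a diagnosis classifier, and whether the generated signals are spectrally
faithful, are empirical questions that require a carefully controlled
pipeline: subject-wise cross-validation (no frames of a test subject in any
training material, including the generator's), exact accounting of the
real/augmented training-set ratios, and frequency-domain evaluation.

`eegaug` implements that pipeline end to end, driven by a seeded
synthetic-cohort generator in place of clinical downloads, so every stage is
testable on a laptop.

## What is inside

| module | contents |
| --- | --- |
| `eegaug.cohort` | seeded synthetic cohorts: 1/f background with delta/alpha peaks and a theta dip, per-group band-power offsets, inter-channel correlation, per-subject spectral jitter, optional spike artifacts |
| `eegaug.preprocess` | 13-channel 10-20 montage intersection, average reference, 1-40 Hz zero-phase band-pass, per-subject z-scaling, 8 s windowing, min/max outlier-window rejection, joint [-1,1] window scaling, balanced subsampling |
| `eegaug.augment` | uniform-noise baseline (±10% of the normalized range, then re-normalized) |
| `eegaug.gan` | conditional Wasserstein GAN: latent-100 generator with four transposed-convolution upsampling stages and tanh output; critic with Gaussian input noise, strided convolutions, dropout and a linear score; weight clipping, 5:1 critic regimen, Adam(5e-4, β₁=0, β₂=0.999, ε=1e-7) |
| `eegaug.classifier` | DeprNet-style CNN (5 × conv/max-pool/batch-norm + 3 dense, sigmoid, binary cross-entropy, Adam(5e-4, β₁=0.9)) with MDD as the positive class |
| `eegaug.evaluate` | leave-two-subjects-out fold planner, the five augmentation-ratio training conditions, periodograms, band powers (delta 0.3-4, theta 4-8, alpha 8-12, beta 12-30 Hz), two-way between-subjects ANOVA, one-sided t-tests, mean ± 95% CI summaries |
| `eegaug.nn` | the numpy neural-network core (conv2d, transposed conv, batch norm, max-pool, dropout, Adam) with hand-derived, gradient-checked backward passes |
| `eegaug.io` / `eegaug.cli` | HDF5 cohort/window containers, GAN checkpoints, optional EDF import (via `mne`), and the `eegaug` command-line group |

The Wasserstein objective is the usual critic/generator pair

```
L_critic = E[f(x̃, y)] − E[f(x, y)]        (minimized, weights clipped to ±c)
L_gen    = −E[f(G(z, y), y)]              (z ~ N(0, I₁₀₀), y ∈ {HC, MDD})
```

with the critic run five times per generator step.

## Worked example

A strongly separable 6+6-subject cohort (alpha rhythm present in HC, absent
in MDD), preprocessed and classified with subject-wise cross-validation
under two training conditions, then checked for spectral neutrality of the
noise baseline:

```python
import numpy as np
from eegaug import (
    SyntheticCohortSpec, generate_cohort, preprocess_cohort,
    AugmentationCondition, ClassifierConfig, run_experiment,
    band_power_table, anova_two_way, NoiseSpec, add_uniform_noise,
)

channels = ("Fp1", "F3", "C3", "P3")
spec = SyntheticCohortSpec(
    n_hc=6, n_mdd=6, sampling_rate=32.0, duration=96.0,
    channel_names=channels,
    alpha_peak={"HC": (10.0, 1.0, 5.0), "MDD": (10.0, 1.0, 0.05)},
    subject_variability=0.2, seed=33,
)
windows, outliers = preprocess_cohort(
    generate_cohort(spec), montage=channels, low=1.0, high=14.0,
    window_seconds=4.0, balance_seed=0,
)
print(f"{windows.n_frames} frames of shape {windows.frame_shape} "
      f"from {len(windows.subjects())} subjects "
      f"({len(outliers)} outlier windows removed)")

report = run_experiment(
    windows,
    conditions=[AugmentationCondition("REAL_100", "noise"),
                AugmentationCondition("REAL_100_AUG_100", "noise")],
    classifier_config=ClassifierConfig(
        conv_filters=(4, 8, 8, 16, 16), dense_units=(32, 16),
        epochs=15, batch_size=32,
    ),
    noise_spec=NoiseSpec(amplitude=0.1),
    seed=0,
)
summary = report.summary()
print(summary[summary.metric == "accuracy"].to_string(index=False))

noise = add_uniform_noise(windows, NoiseSpec(0.1, seed=0))
table = band_power_table(windows, noise)
res = anova_two_way(table, "alpha")
print(f"alpha band, diagnosis effect: F(1,{res['diagnosis'].df[1]}) = "
      f"{res['diagnosis'].statistic:.2f}, p = {res['diagnosis'].p_value:.4f}")
print(f"alpha band, data-type effect: F(1,{res['data_type'].df[1]}) = "
      f"{res['data_type'].statistic:.2f}, p = {res['data_type'].p_value:.4f}")
```

Output:

```
240 frames of shape (4, 128) from 12 subjects (26 outlier windows removed)
       condition   metric     mean   ci_low  ci_high
        REAL_100 accuracy 0.966667 0.930822 1.002512
REAL_100_AUG_100 accuracy 0.966667 0.934893 0.998440
alpha band, diagnosis effect: F(1,20) = 3825.85, p = 0.0000
alpha band, data-type effect: F(1,20) = 0.44, p = 0.5161
```

Reading: the classifier recovers the injected group difference almost
perfectly (96.7% mean accuracy over 6 folds, each testing one held-out HC
and one held-out MDD subject); padding the training set with an equal amount
of noise-augmented frames neither helps nor hurts on this easy cohort. The
ANOVA confirms a massive diagnosis effect on alpha power and no real-vs-noise
difference — the noise baseline is spectrally neutral at band granularity.

The same experiment with `AugmentationCondition(..., "synthetic")` retrains
the conditional WGAN inside every fold (on that fold's training subjects
only) and augments with generated frames instead.

## Command line

```bash
eegaug simulate --config cohort.yaml --out cohort.h5
eegaug preprocess --in cohort.h5 --out windows.h5 --config pre.yaml
eegaug augment-noise --in windows.h5 --out noise.h5 --amplitude 0.1 --seed 1
eegaug train-gan --in windows.h5 --config gan.yaml --out ckpt
eegaug sample --ckpt ckpt --n 100 --label MDD --seed 1 --out synth.h5
eegaug classify --train windows.h5 --test test.h5 --report metrics.csv
eegaug evaluate --real windows.h5 --source noise --conditions all --out results/
```

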