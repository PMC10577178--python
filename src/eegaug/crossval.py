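"""Leave-two-subjects-out cross-validation and the augmentation-ratio study.

Each test fold holds exactly one HC and one MDD subject (all of their
frames); all remaining subjects train. Pairing is by sorted subject id, so
the plan is deterministic. Five training conditions are realized per fold:

====================  =====================================================
REAL_100              all real training frames
AUG_100_ONLY          augmented frames only, same count as the real frames
REAL_50_AUG_50        half the real frames (group-stratified) + equal count
                      of augmented frames
REAL_100_AUG_100      all real frames + the same count of augmented frames
REAL_100_AUG_200      all real frames + twice that count of augmented frames
====================  =====================================================

Test data is always the fold's untouched real frames. For the synthetic
source the GAN is retrained per fold on that fold's training subjects only,
so generated frames never carry information from the fold's test subjects;
a faster train-once mode exists but leaks test subjects into the generator
and is flagged with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gan as gan_mod
from .augment import NoiseSpec, add_uniform_noise
from .classifier import ClassifierConfig, evaluate, train_classifier
from .containers import EEGError, WindowSet
from .stats import summarize

CONDITION_IDS = (
    "REAL_100",
    "AUG_100_ONLY",
    "REAL_50_AUG_50",
    "REAL_100_AUG_100",
    "REAL_100_AUG_200",
)


@dataclass(frozen=True)
class AugmentationCondition:
    id: str
    source: str = "noise"  # "noise" or "synthetic"

    def __post_init__(self) -> None:
        if self.id not in CONDITION_IDS:
            raise EEGError(f"unknown condition {self.id!r}")
        if self.source not in ("noise", "synthetic"):
            raise EEGError(f"unknown augmentation source {self.source!r}")


@dataclass(frozen=True)
class Fold:
    test_hc: str
    test_mdd: str
    train: tuple[str, ...]

    @property
    def test(self) -> tuple[str, str]:
        return (self.test_hc, self.test_mdd)


@dataclass(frozen=True)
class FoldPlan:
    folds: tuple[Fold, ...]
    pairing_rule: str = "sorted-id"
    seed: int = 0


def make_fold_plan(subject_groups: Mapping[str, str], seed: int = 0) -> FoldPlan:
    """One fold per sorted HC-MDD pair; every subject tests exactly once."""
    hc = sorted(s for s, g in subject_groups.items() if g == "HC")
    mdd = sorted(s for s, g in subject_groups.items() if g == "MDD")
    unknown = {g for g in subject_groups.values()} - {"HC", "MDD"}
    if unknown:
        raise EEGError(f"unknown groups {sorted(unknown)}")
    if len(hc) != len(mdd):
        raise EEGError(
            f"groups must be balanced: {len(hc)} HC vs {len(mdd)} MDD"
        )
    if len(hc) < 2:
        raise EEGError("need at least 2 subjects per group")
    everyone = hc + mdd
    folds = []
    for h, m in zip(hc, mdd):
        train = tuple(s for s in everyone if s not in (h, m))
        folds.append(Fold(test_hc=h, test_mdd=m, train=train))
    return FoldPlan(folds=tuple(folds), seed=seed)


def _stratified_pick(
    ws: WindowSet, per_group: Mapping[str, int], rng: np.random.Generator
) -> WindowSet:
    picks: list[int] = []
    for grp, k in per_group.items():
        idx = np.flatnonzero(ws.groups == grp)
        if idx.size < k:
            raise EEGError(
                f"insufficient augmented frames for group {grp}: "
                f"have {idx.size}, need {k}"
            )
        sel = rng.choice(idx.size, size=k, replace=False)
        picks.extend(idx[i] for i in sorted(sel))
    return ws.select(np.array(picks))


def build_training_set(
    fold: Fold,
    condition: AugmentationCondition,
    real: WindowSet,
    augmented: WindowSet | None,
    seed: int = 0,
) -> WindowSet:
    """Realize one condition's frame counts for one fold.

    Augmented frames are drawn (seeded, without replacement) with the same
    group composition as the real frames they complement. Frames of the
    fold's test subjects never enter, regardless of source.
    """
    rng = np.random.default_rng(seed)
    train_mask = np.isin(real.subject_ids.astype(str), fold.train)
    base = real.select(train_mask)
    if base.n_frames == 0:
        raise EEGError("fold has no real training frames")
    group_counts = {g: int(np.sum(base.groups == g)) for g in ("HC", "MDD")}

    if condition.id == "REAL_100":
        real_part, aug_counts = base, None
    elif condition.id == "AUG_100_ONLY":
        real_part, aug_counts = None, dict(group_counts)
    elif condition.id == "REAL_50_AUG_50":
        half = {g: c // 2 for g, c in group_counts.items()}
        real_part = _stratified_pick(base, half, rng)
        aug_counts = dict(half)
    elif condition.id == "REAL_100_AUG_100":
        real_part, aug_counts = base, dict(group_counts)
    elif condition.id == "REAL_100_AUG_200":
        real_part, aug_counts = base, {g: 2 * c for g, c in group_counts.items()}
    else:  # pragma: no cover - guarded by AugmentationCondition
        raise EEGError(condition.id)

    parts = [] if real_part is None else [real_part]
    if aug_counts is not None:
        if augmented is None:
            raise EEGError(f"condition {condition.id} needs augmented frames")
        test_subjects = set(fold.test)
        if any(str(s) in test_subjects for s in augmented.subject_ids):
            raise EEGError(
                "augmented frames derived from the fold's test subjects"
            )
        parts.append(_stratified_pick(augmented, aug_counts, rng))
    return WindowSet.concat(parts)


@dataclass
class ClassificationReport:
    """Per-fold metrics plus mean and 95% CI per condition (MDD positive)."""

    per_fold: pd.DataFrame
    conditions: tuple[AugmentationCondition, ...]
    positive_class: str = "MDD"
    fold_plan: FoldPlan | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for cond_id, grp in self.per_fold.groupby("condition", observed=True):
            for metric in ("accuracy", "precision", "recall", "specificity"):
                mean, (lo, hi) = summarize(grp[metric].to_numpy())
                rows.append({
                    "condition": cond_id, "metric": metric,
                    "mean": mean, "ci_low": lo, "ci_high": hi,
                })
        return pd.DataFrame(rows)

    def accuracies(self, condition_id: str) -> np.ndarray:
        sub = self.per_fold[self.per_fold["condition"] == condition_id]
        return sub["accuracy"].to_numpy()


def run_experiment(
    real: WindowSet,
    *,
    conditions: Sequence[AugmentationCondition],
    classifier_config: ClassifierConfig,
    noise_spec: NoiseSpec | None = None,
    gan_generator_spec: gan_mod.GeneratorSpec | None = None,
    gan_critic_spec: gan_mod.CriticSpec | None = None,
    gan_config: gan_mod.GanTrainingConfig | None = None,
    gan_bundle: gan_mod.GanBundle | None = None,
    retrain_gan_per_fold: bool = True,
    seed: int = 0,
) -> ClassificationReport:
    """Full fold x condition sweep; classifiers always test on real frames.

    Noise augmentation is derived per fold from that fold's training frames.
    Synthetic augmentation retrains the GAN per fold on the training
    subjects by default; passing a prebuilt ``gan_bundle`` with
    ``retrain_gan_per_fold=False`` skips this but leaks the test subjects
    through the generator (a warning is issued).
    """
    conditions = tuple(conditions)
    groups = {str(s): str(real.groups[real.subject_ids == s][0])
              for s in real.subjects()}
    plan = make_fold_plan(groups, seed=seed)
    need_noise = any(c.source == "noise" and c.id != "REAL_100" for c in conditions)
    need_synth = any(c.source == "synthetic" and c.id != "REAL_100"
                     for c in conditions)
    if need_synth and not retrain_gan_per_fold:
        if gan_bundle is None:
            raise EEGError("train-once mode needs a prebuilt gan_bundle")
        warnings.warn(
            "Reusing one GAN across folds leaks test subjects into the "
            "generator; accuracies may be optimistic.",
            UserWarning,
            stacklevel=2,
        )
    if need_synth and retrain_gan_per_fold and (
        gan_generator_spec is None or gan_critic_spec is None or gan_config is None
    ):
        raise EEGError("per-fold GAN retraining needs generator/critic specs "
                       "and a training config")

    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(len(plan.folds) * 4).reshape(-1, 4)
    rows = []
    for f_idx, fold in enumerate(plan.folds):
        s_noise, s_gan, s_build, s_clf = (int(v) for v in fold_seeds[f_idx])
        train_mask = np.isin(real.subject_ids.astype(str), fold.train)
        fold_train = real.select(train_mask)
        fold_test = real.select(~train_mask)
        n_train = fold_train.n_frames

        noise_ws = None
        if need_noise:
            spec = noise_spec or NoiseSpec()
            passes = [
                add_uniform_noise(
                    fold_train, NoiseSpec(spec.amplitude, seed=s_noise + rep)
                )
                for rep in range(2)  # enough for the 200% condition
            ]
            noise_ws = WindowSet.concat(passes)

        synth_ws = None
        if need_synth:
            if retrain_gan_per_fold:
                cfg = gan_mod.GanTrainingConfig(
                    **{**gan_config.__dict__, "seed": s_gan}
                )
                bundle = gan_mod.train(
                    fold_train, gan_generator_spec, gan_critic_spec, cfg
                )
            else:
                bundle = gan_bundle
            per_group = {g: int(np.sum(fold_train.groups == g))
                         for g in ("HC", "MDD")}
            synth_ws = WindowSet.concat([
                gan_mod.sample(bundle, 2 * per_group[g], g, seed=s_gan + k)
                for k, g in enumerate(("HC", "MDD"))
            ])

        for c_idx, cond in enumerate(conditions):
            augmented = noise_ws if cond.source == "noise" else synth_ws
            training = build_training_set(
                fold, cond, real, augmented, seed=s_build + c_idx
            )
            # subject-wise integrity: no test-subject frame may train
            assert not set(map(str, training.subject_ids)) & set(fold.test)
            cfg = ClassifierConfig(
                **{**classifier_config.__dict__, "seed": s_clf + c_idx}
            )
            model, _ = train_classifier(training, cfg)
            metrics = evaluate(model, fold_test, cfg.decision_threshold)
            rows.append({
                "fold": f_idx, "test_hc": fold.test_hc, "test_mdd": fold.test_mdd,
                "condition": cond.id, "source": cond.source,
                "n_train_frames": training.n_frames, **metrics,
            })
    return ClassificationReport(
        per_fold=pd.DataFrame(rows), conditions=conditions, fold_plan=plan
    )
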