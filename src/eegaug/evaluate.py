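"""Umbrella evaluation surface: CV experiment, spectra and statistics."""

from .crossval import (
    CONDITION_IDS,
    AugmentationCondition,
    ClassificationReport,
    Fold,
    FoldPlan,
    build_training_set,
    make_fold_plan,
    run_experiment,
)
from .spectral import (
    band_power,
    band_power_table,
    frame_spectra,
    match_synthetic_units,
    mean_spectrum_with_ci,
    periodogram,
    subject_mean_spectrum,
)
from .stats import StatResult, anova_two_way, one_sided_ttest, summarize

__all__ = [
    "CONDITION_IDS",
    "AugmentationCondition",
    "ClassificationReport",
    "Fold",
    "FoldPlan",
    "StatResult",
    "anova_two_way",
    "band_power",
    "band_power_table",
    "build_training_set",
    "frame_spectra",
    "make_fold_plan",
    "match_synthetic_units",
    "mean_spectrum_with_ci",
    "one_sided_ttest",
    "periodogram",
    "run_experiment",
    "subject_mean_spectrum",
    "summarize",
]
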