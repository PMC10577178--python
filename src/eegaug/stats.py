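"""Statistical machinery: two-way ANOVA, one-sided t-tests, summaries.

The band-power ANOVA is a fixed-effects two-way design with between-subjects
factors data type (real/synthetic or real/noise) and diagnosis (HC/MDD),
evaluated on a balanced table; F statistics carry (1, N-4) denominator
degrees of freedom. Accuracy comparisons use one-sided t-tests at alpha =
0.05, not corrected for multiple comparisons: pooled-variance two-sample
when comparing two training conditions (df = n_a + n_b - 2) and one-sample
against chance 0.5 (df = n - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

from .containers import EEGError


@dataclass(frozen=True)
class StatResult:
    test_id: str
    statistic: float
    df: tuple[int, ...]
    p_value: float
    sided: str  # "two", "greater" or "less"
    alpha: float = 0.05
    corrected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise EEGError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def anova_two_way(table: pd.DataFrame, band: str) -> dict[str, StatResult]:
    """Two-way between-subjects ANOVA on one band of a band-power table.

    Requires a balanced design with all four (data_type x diagnosis) cells
    populated. Returns the data-type main effect, the diagnosis main effect
    and their interaction.
    """
    sub = table[table["band"] == band]
    if sub.empty:
        raise EEGError(f"band {band!r} not present in table")
    cells = sub.groupby(["data_type", "diagnosis"], observed=True).size()
    if len(cells) != 4:
        raise EEGError("all four data_type x diagnosis cells must be populated")
    if cells.nunique() != 1:
        raise EEGError("design must be balanced (equal cell counts)")
    if np.ptp(sub["power"].to_numpy()) == 0:
        raise EEGError("degenerate table: all band powers identical")

    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("power ~ C(data_type) * C(diagnosis)", data=sub).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    n = len(sub)
    df_den = n - 4
    out = {}
    for key, row_name in (
        ("data_type", "C(data_type)"),
        ("diagnosis", "C(diagnosis)"),
        ("interaction", "C(data_type):C(diagnosis)"),
    ):
        out[key] = StatResult(
            test_id=f"anova:{band}:{key}",
            statistic=float(aov.loc[row_name, "F"]),
            df=(1, df_den),
            p_value=float(aov.loc[row_name, "PR(>F)"]),
            sided="two",
        )
    return out


def one_sided_ttest(
    acc_a: np.ndarray,
    acc_b: np.ndarray | None = None,
    *,
    chance: float = 0.5,
    alternative: str = "greater",
    test_id: str = "ttest",
) -> StatResult:
    """One-sided t-test on per-fold accuracies.

    Two samples: pooled-variance two-sample test of ``acc_a`` vs ``acc_b``
    (df = n_a + n_b - 2). One sample: test of ``acc_a`` against the chance
    level (df = n - 1).
    """
    a = np.asarray(acc_a, dtype=float)
    if a.size < 2:
        raise EEGError("need at least 2 observations per sample")
    if acc_b is None:
        res = st.ttest_1samp(a, popmean=chance, alternative=alternative)
        df = (a.size - 1,)
        delta = a.mean() - chance
    else:
        b = np.asarray(acc_b, dtype=float)
        if b.size < 2:
            raise EEGError("need at least 2 observations per sample")
        res = st.ttest_ind(a, b, equal_var=True, alternative=alternative)
        df = (a.size + b.size - 2,)
        delta = a.mean() - b.mean()
    statistic, p_value = float(res.statistic), float(res.pvalue)
    if np.isnan(statistic):
        # zero pooled variance: the t statistic degenerates to a sign test
        if delta == 0.0:
            statistic, p_value = 0.0, 0.5
        else:
            statistic = np.inf * np.sign(delta)
            wins = (delta > 0) if alternative == "greater" else (delta < 0)
            p_value = 0.0 if wins else 1.0
    return StatResult(
        test_id=test_id,
        statistic=statistic,
        df=df,
        p_value=p_value,
        sided=alternative,
    )


def summarize(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Mean with 95% t-based confidence interval."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise EEGError("need at least 2 values to summarize")
    mean = float(v.mean())
    half = float(st.t.ppf(0.975, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size))
    return mean, (mean - half, mean + half)
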