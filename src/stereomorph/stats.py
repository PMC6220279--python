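"""Shared statistical engine.

Normality gating (Shapiro-Wilk), two-sample t-tests computed either from raw
samples or from printed summary statistics, two-way ANOVA with Tukey and
Bonferroni post hoc comparisons, and pairwise-complete Pearson correlation.

Group comparisons in the rest of the package funnel through
:func:`two_sample_test` so that the pooled and Welch variants are always
co-reported: published group differences are frequently given only as
(mean, SD, n) triples, and the two conventions can disagree near a
significance boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "NormalityResult",
    "GroupTestResult",
    "AnovaResult",
    "normality_gate",
    "two_sample_test",
    "summary_ttest",
    "two_way_anova",
    "pearson_matrix",
]


@dataclass(frozen=True)
class NormalityResult:
    """Shapiro-Wilk test outcome used as a gate before t-tests."""

    W: float
    p: float
    passed: bool
    n: int
    supported: bool
    reason: str = ""


@dataclass(frozen=True)
class GroupTestResult:
    """A two-sample comparison under one variance convention."""

    kind: str  # "pooled" or "welch"
    t: float
    df: float
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    flagged: str = ""


@dataclass
class AnovaResult:
    """Two-way ANOVA effects plus post hoc pairwise tables."""

    table: pd.DataFrame  # index: factor/interaction; columns F, df, p
    tukey: pd.DataFrame
    bonferroni: pd.DataFrame
    interaction_dropped: bool = False
    warnings: list[str] = field(default_factory=list)


def normality_gate(sample: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk normality test with a pass/fail gate at ``p > alpha``.

    The W statistic uses the Royston coefficient approximation (scipy's
    implementation).  Sample sizes outside 3..50 are still computed but
    flagged unsupported; a constant sample has undefined W and fails the
    gate with a reason.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 3:
        return NormalityResult(np.nan, np.nan, False, n, False, "n < 3")
    if np.ptp(x) == 0:
        return NormalityResult(np.nan, np.nan, False, n, 3 <= n <= 50,
                               "constant sample: W undefined")
    W, p = sps.shapiro(x)
    supported = 3 <= n <= 50
    reason = "" if supported else "n outside 3..50 coefficient table"
    return NormalityResult(float(W), float(p), bool(p > alpha), n, supported, reason)


def _t_from_summaries(mean1: float, sd1: float, n1: int,
                      mean2: float, sd2: float, n2: int,
                      variant: str) -> tuple[float, float, float, str]:
    """Closed-form t statistic, df and two-sided p from (mean, SD, n) pairs."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    v1, v2 = sd1 ** 2, sd2 ** 2
    flag = ""
    if v1 == 0 and v2 == 0:
        # degenerate: no within-group variability at all
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0, "zero variance, equal means: p=1 by convention"
        return np.inf, float(n1 + n2 - 2), 0.0, "zero variance, unequal means"
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = np.sqrt(se2_1 + se2_2)
        df = (se2_1 + se2_2) ** 2 / (
            se2_1 ** 2 / (n1 - 1) + se2_2 ** 2 / (n2 - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p), flag


def summary_ttest(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int,
                  variant: str = "pooled") -> GroupTestResult:
    """Two-sample t-test from printed summary statistics."""
    t, df, p, flag = _t_from_summaries(mean1, sd1, n1, mean2, sd2, n2, variant)
    return GroupTestResult(variant, t, df, p, mean1, sd1, n1, mean2, sd2, n2, flag)


def two_sample_test(sample1: Sequence[float] | None = None,
                    sample2: Sequence[float] | None = None,
                    summaries: tuple | None = None,
                    variant: str = "pooled") -> GroupTestResult:
    """Two-sample t-test from raw data or from ``((m1, sd1, n1), (m2, sd2, n2))``.

    The raw-data path reduces the samples to their summaries and calls the
    same closed form, so the two entry paths agree exactly.  SDs use the
    n-1 (sample) convention.
    """
    if summaries is not None:
        (m1, s1, n1), (m2, s2, n2) = summaries
        return summary_ttest(m1, s1, n1, m2, s2, n2, variant)
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    return summary_ttest(float(x.mean()), float(x.std(ddof=1)), x.size,
                         float(y.mean()), float(y.std(ddof=1)), y.size,
                         variant)


def two_way_anova(values: Sequence[float],
                  factor_a: Sequence,
                  factor_b: Sequence,
                  names: tuple[str, str] = ("genotype", "layer")) -> AnovaResult:
    """Two-way ANOVA (type-II sums of squares) with Tukey HSD post hoc.

    ``factor_a`` is typically genotype and ``factor_b`` the cortical layer
    band.  Post hoc tables compare genotype within each level of
    ``factor_b``: Tukey HSD over all cell means, plus Bonferroni-adjusted
    pairwise pooled t-tests per layer (both labeled, since published work
    often mixes the two conventions).  The interaction term is dropped with
    a warning when any design cell is empty or has a single observation.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "A": pd.Categorical(factor_a),
                       "B": pd.Categorical(factor_b)})
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")
    cell_counts = df.groupby(["A", "B"], observed=False).size()
    warnings: list[str] = []
    with_interaction = bool((cell_counts >= 2).all())
    if not with_interaction:
        warnings.append("interaction dropped: some cell has < 2 observations")
    formula = "y ~ C(A) * C(B)" if with_interaction else "y ~ C(A) + C(B)"
    fit = ols(formula, data=df).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    rename = {"C(A)": names[0], "C(B)": names[1],
              "C(A):C(B)": f"{names[0]}:{names[1]}", "Residual": "residual"}
    aov = aov.rename(index=rename)

    cell_label = df["A"].astype(str) + "|" + df["B"].astype(str)
    tk = pairwise_tukeyhsd(df["y"].to_numpy(), cell_label.to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])

    # Bonferroni-adjusted genotype contrasts within each B level
    rows = []
    levels_a = list(df["A"].cat.categories)
    levels_b = list(df["B"].cat.categories)
    m = len(levels_b)
    for b in levels_b:
        sub = df[df["B"] == b]
        g1 = sub.loc[sub["A"] == levels_a[0], "y"].to_numpy()
        g2 = sub.loc[sub["A"] == levels_a[1], "y"].to_numpy()
        if len(g1) < 2 or len(g2) < 2:
            continue
        res = two_sample_test(g1, g2, variant="pooled")
        rows.append({names[1]: b, "t": res.t, "df": res.df, "p_raw": res.p,
                     "p_bonf": min(1.0, res.p * m)})
    bonf = pd.DataFrame(rows)
    return AnovaResult(aov, tukey, bonf, not with_interaction, warnings)


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of columns.

    Zero-variance columns yield NaN rows/columns (flagged by NaN rather
    than silently set to 0).  Requires at least 3 observations.
    """
    if len(table) < 3:
        raise ValueError("pearson_matrix needs >= 3 observations (rows)")
    corr = table.corr(method="pearson", min_periods=3)
    # enforce exact unit diagonal where the column has variance
    for c in corr.columns:
        if table[c].std(ddof=1) > 0:
            corr.loc[c, c] = 1.0
    return corr
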