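"""Cohort-level statistics across the four progression metrics.

A one-way within-subjects (repeated-measures) ANOVA compares the per-eye
slopes (or baseline means) of MMS, ESS, mFTP and HRS, followed — when the
omnibus test is significant — by Bonferroni-corrected paired t-tests for
the 6 metric pairs.  No sphericity correction is applied by default; a
Greenhouse–Geisser option is available.  Eyes missing a metric (e.g. an
empty edge-of-scotoma selection) are dropped listwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "AnovaResult",
    "PairwiseEntry",
    "rm_anova",
    "bonferroni_pairwise",
    "compare_metrics",
    "baseline_age_fit",
]


@dataclass(frozen=True)
class PairwiseEntry:
    pair: tuple[str, str]
    mean_diff: float
    t: float
    p_raw: float
    p_bonferroni: float   # min(1, m * p_raw)
    degenerate: bool = False


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df: tuple[float, float]
    p: float
    n_subjects: int
    pairwise: tuple[PairwiseEntry, ...] | None = None


def _complete_cases(matrix: pd.DataFrame) -> pd.DataFrame:
    m = pd.DataFrame(matrix).dropna()
    if m.shape[0] < 2:
        raise ValueError(
            f"repeated-measures ANOVA needs >= 2 complete-case subjects, got {m.shape[0]}"
        )
    return m


def rm_anova(matrix: pd.DataFrame, gg_correction: bool = False) -> AnovaResult:
    """One-way within-subjects ANOVA over the columns of ``matrix``.

    ``matrix`` is subjects × conditions (eyes × metrics).  F = MS_cond /
    MS_error with df (k−1, (k−1)(n−1)); rows with any missing value are
    dropped.  When every subject has identical values across conditions both
    mean squares vanish; that degenerate case is reported as F = 0, p = 1.
    With ``gg_correction`` the Greenhouse–Geisser epsilon rescales the
    degrees of freedom of the p-value.
    """
    m = _complete_cases(matrix)
    n, k = m.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    # Degenerate guard: with the subject effect removed, no variance is left
    # to test (all columns identical within every subject) -> F = 0, p = 1.
    within = m.values - m.values.mean(axis=1, keepdims=True)
    df = (k - 1.0, (k - 1.0) * (n - 1.0))
    if np.allclose(within, 0.0, atol=1e-12):
        return AnovaResult(F=0.0, df=df, p=1.0, n_subjects=n)
    long = m.reset_index(names="subject").melt(
        id_vars="subject", var_name="condition", value_name="value"
    )
    res = AnovaRM(long, depvar="value", subject="subject", within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    F = float(row["F Value"])
    df1, df2 = float(row["Num DF"]), float(row["Den DF"])
    p = float(row["Pr > F"])
    if gg_correction:
        eps = _gg_epsilon(m.values)
        p = float(_stats.f.sf(F, eps * df1, eps * df2))
    return AnovaResult(F=F, df=(df1, df2), p=p, n_subjects=n)


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the condition covariance matrix."""
    k = x.shape[1]
    s = np.cov(x, rowvar=False)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(s.mean(axis=1) ** 2)
                     + k**2 * mean_all**2)
    return float(num / den) if den > 0 else 1.0


def bonferroni_pairwise(
    matrix: pd.DataFrame, omnibus_significant: bool = True
) -> tuple[PairwiseEntry, ...]:
    """Paired t-tests for every column pair with Bonferroni correction.

    Corrected p = min(1, m·p_raw) for m = k(k−1)/2 pairs.  Post hoc tests are
    conventionally run only after a significant omnibus ANOVA; pass
    ``omnibus_significant=False`` to acknowledge running them anyway.  A pair
    whose paired differences have zero variance is reported as a degenerate
    sentinel (NaN t and p) rather than an arbitrary extreme statistic.
    """
    m = _complete_cases(matrix)
    cols = list(m.columns)
    n_pairs = len(cols) * (len(cols) - 1) // 2
    entries = []
    for a, b in itertools.combinations(cols, 2):
        d = m[a].values - m[b].values
        if np.ptp(d) == 0:
            if np.all(d == 0):
                # identical columns: t = 0, no evidence of a difference
                entries.append(PairwiseEntry((a, b), 0.0, 0.0, 1.0, 1.0))
            else:
                # constant nonzero difference: t undefined (zero variance)
                entries.append(
                    PairwiseEntry((a, b), float(np.mean(d)), math.nan, math.nan,
                                  math.nan, degenerate=True)
                )
            continue
        t, p = _stats.ttest_rel(m[a].values, m[b].values)
        entries.append(
            PairwiseEntry(
                (a, b),
                float(np.mean(d)),
                float(t),
                float(p),
                min(1.0, n_pairs * float(p)),
            )
        )
    return tuple(entries)


def compare_metrics(
    matrix: pd.DataFrame, alpha: float = 0.05, gg_correction: bool = False
) -> AnovaResult:
    """Omnibus RM-ANOVA plus pairwise post hocs when the omnibus is significant."""
    res = rm_anova(matrix, gg_correction=gg_correction)
    pairwise = (
        bonferroni_pairwise(matrix) if res.p < alpha else None
    )
    return AnovaResult(res.F, res.df, res.p, res.n_subjects, pairwise)


def baseline_age_fit(values: np.ndarray, ages: np.ndarray):
    """OLS of a baseline metric against age: slope, intercept, R².

    Returns ``(slope, intercept, r_squared, formula)`` with the formula
    formatted as the conventional ``y = ax + b`` report.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) != len(ages) or len(values) < 3:
        raise ValueError("need >= 3 paired (value, age) observations")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; slope undefined")
    fit = _stats.linregress(ages, values)
    r2 = float(fit.rvalue**2)
    formula = f"y = {fit.slope:.2f}x + {fit.intercept:.2f}"
    return float(fit.slope), float(fit.intercept), r2, formula
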