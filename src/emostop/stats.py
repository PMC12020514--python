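"""Inference layer: t-tests, effect sizes, split-plot ANOVA, power.

Covers the statistics used to analyse the stop-signal outcomes:

* independent-samples t-tests in pooled and Welch forms, computable from
  raw samples or from published summary statistics (mean, SD, n), with
  Cohen's d on the pooled SD;
* a Levene gate choosing Welch when group variances differ at α = 0.05;
* the 2 (age group, between) × 2 (stop-signal valence, within) mixed
  ANOVA via the classical split-plot sums-of-squares decomposition, with
  partial eta squared per effect, plus a covariate-adjusted variant with
  the covariate entered in the between-subjects stratum;
* a-priori power for the within-between interaction via the noncentral
  F distribution, with the noncentrality convention
  λ = f²·N·(m·ε)/(1−ρ) of the standard power tools.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "TestResult",
    "PowerSpec",
    "summarize",
    "ttest_from_summary",
    "ttest_raw",
    "cohens_d",
    "levene_gate",
    "mixed_anova_2x2",
    "ancova_2x2_mixed",
    "power_within_between",
    "power_min_n",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean, SD and n of one group on one measure."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary statistics need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_size: Optional[float]
    method: str

    @property
    def df1(self) -> float:
        return self.df[0] if isinstance(self.df, tuple) else 1.0

    @property
    def df2(self) -> float:
        return self.df[1] if isinstance(self.df, tuple) else self.df


def summarize(x: Sequence[float]) -> SummaryStats:
    x = np.asarray(x, dtype=float)
    return SummaryStats(mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)), n=int(x.size))


def _pooled_sd(a: SummaryStats, b: SummaryStats) -> float:
    num = (a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2
    return math.sqrt(num / (a.n + b.n - 2))


def ttest_from_summary(
    a: SummaryStats, b: SummaryStats, variant: str = "pooled"
) -> TestResult:
    """Two-sample t-test from summary statistics, two-tailed.

    ``variant='pooled'`` is the classical equal-variance test with
    df = n₁+n₂−2; ``'welch'`` uses per-group variances with
    Welch–Satterthwaite df. Effect size is Cohen's d on the pooled SD
    in both variants.
    """
    diff = a.mean - b.mean
    if variant == "pooled":
        sp = _pooled_sd(a, b)
        se = sp * math.sqrt(1 / a.n + 1 / b.n)
        df = float(a.n + b.n - 2)
    elif variant == "welch":
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1)) if se > 0 else float(
            a.n + b.n - 2
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if se == 0:
        t = 0.0 if diff == 0 else math.inf * math.copysign(1, diff)
    else:
        t = diff / se
    p = float(2 * sps.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    if t == 0:
        p = 1.0
    d = cohens_d(a, b) if _pooled_sd(a, b) > 0 else None
    return TestResult(statistic=float(t), df=float(df), p=p, effect_size=d, method=f"t-{variant}")


def ttest_raw(x: Sequence[float], y: Sequence[float], variant: str = "pooled") -> TestResult:
    """Two-sample t-test on raw observations (delegates to the summary form)."""
    return ttest_from_summary(summarize(x), summarize(y), variant)


def cohens_d(a: SummaryStats, b: SummaryStats) -> float:
    """Standardized mean difference |m₁−m₂| / pooled SD."""
    sp = _pooled_sd(a, b)
    if sp == 0:
        raise ValueError("Cohen's d undefined: zero pooled variance")
    return abs(a.mean - b.mean) / sp


def levene_gate(
    *groups: Sequence[float], alpha: float = 0.05
) -> tuple[TestResult, str]:
    """Levene's test (mean-centred) deciding pooled vs Welch.

    Returns the Levene result and ``'welch'`` when the homogeneity
    hypothesis is rejected at ``alpha``, else ``'pooled'``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in arrays):
        raise ValueError("every group needs at least two observations")
    stat, p = sps.levene(*arrays, center="mean")
    k, n = len(arrays), sum(g.size for g in arrays)
    res = TestResult(
        statistic=float(stat),
        df=(float(k - 1), float(n - k)),
        p=float(p),
        effect_size=None,
        method="levene-mean",
    )
    return res, ("welch" if p < alpha else "pooled")


def _anova_frame(
    data: pd.DataFrame, subject: str, between: str, within: str, value: str
) -> pd.DataFrame:
    df = data[[subject, between, within, value]].copy()
    wide = df.pivot(index=subject, columns=within, values=value)
    if wide.isna().any().any() or wide.shape[1] != 2:
        raise ValueError("every participant must contribute exactly one value per condition")
    groups = df.groupby(subject)[between].nunique()
    if (groups != 1).any():
        raise ValueError("participants must each belong to a single group")
    if df[between].nunique() != 2:
        raise ValueError("exactly two between-subject groups are required")
    return df


def _f_result(ss_effect: float, df_effect: float, ss_error: float, df_error: float, method: str) -> TestResult:
    if ss_effect <= 0 or df_error <= 0:
        return TestResult(0.0, (df_effect, df_error), 1.0, 0.0, method)
    ms_effect = ss_effect / df_effect
    ms_error = ss_error / df_error
    if ms_error == 0:
        return TestResult(math.inf, (df_effect, df_error), 0.0, 1.0, method)
    f = ms_effect / ms_error
    p = float(sps.f.sf(f, df_effect, df_error))
    eta = ss_effect / (ss_effect + ss_error)
    return TestResult(float(f), (df_effect, df_error), p, float(eta), method)


def mixed_anova_2x2(
    data: pd.DataFrame,
    subject: str = "participant_id",
    between: str = "group",
    within: str = "condition",
    value: str = "value",
) -> dict[str, TestResult]:
    """2×2 split-plot ANOVA (one between factor, one within factor).

    Classical decomposition: the between-groups effect is tested against
    subjects-within-groups; the within effect and the interaction
    against the condition × subject-within-groups residual. Effect sizes
    are partial eta squared, SS_effect / (SS_effect + SS_error-of-that-
    effect). Returns ``{'between': ..., 'within': ..., 'interaction': ...}``.
    """
    df = _anova_frame(data, subject, between, within, value)
    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    m = df[within].nunique()
    subj_means = df.groupby(subject)[value].mean()
    subj_group = df.groupby(subject)[between].first()
    n_subjects = len(subj_means)
    n_per_group = subj_group.value_counts()

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(m * ((subj_means - grand) ** 2).sum())
    group_means = df.groupby(between)[value].mean()
    ss_group = float(
        m * sum(n_per_group[g] * (group_means[g] - grand) ** 2 for g in group_means.index)
    )
    ss_subj_within = ss_between_subj - ss_group

    cond_means = df.groupby(within)[value].mean()
    ss_condition = float(n_subjects * ((cond_means - grand) ** 2).sum())
    cell_means = df.groupby([between, within])[value].mean()
    ss_interaction = 0.0
    for (g, c), cell in cell_means.items():
        ss_interaction += n_per_group[g] * (cell - group_means[g] - cond_means[c] + grand) ** 2
    ss_interaction = float(ss_interaction)
    ss_error_within = (
        ss_total - ss_group - ss_subj_within - ss_condition - ss_interaction
    )
    ss_error_within = max(ss_error_within, 0.0)

    g_levels = 2
    df_group, df_subj = g_levels - 1, n_subjects - g_levels
    df_cond = m - 1
    df_int = df_group * df_cond
    df_err_within = (n_subjects - g_levels) * (m - 1)
    return {
        "between": _f_result(ss_group, df_group, ss_subj_within, df_subj, "mixed-anova between"),
        "within": _f_result(ss_condition, df_cond, ss_error_within, df_err_within, "mixed-anova within"),
        "interaction": _f_result(
            ss_interaction, df_int, ss_error_within, df_err_within, "mixed-anova interaction"
        ),
    }


def _ols_sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def ancova_2x2_mixed(
    data: pd.DataFrame,
    covariate: pd.Series | dict,
    subject: str = "participant_id",
    between: str = "group",
    within: str = "condition",
    value: str = "value",
) -> dict[str, TestResult]:
    """Mixed ANOVA with a subject-level covariate in the between stratum.

    The covariate adjusts the between-subjects (group) test: subject
    means are modelled as intercept + covariate + group, and the group
    effect is the Type-III sum of squares against the residual with
    N−3 df. Covariate × factor interactions are excluded, so the
    within-subject contrasts (condition, interaction) are unchanged
    from :func:`mixed_anova_2x2`. A constant covariate degrades to the
    plain ANOVA with a warning.
    """
    df = _anova_frame(data, subject, between, within, value)
    cov = pd.Series(covariate)
    subj_means = df.groupby(subject)[value].mean()
    missing = subj_means.index.difference(cov.index)
    if len(missing):
        raise ValueError(f"covariate missing for participants: {sorted(missing)[:5]}")
    x = cov.loc[subj_means.index].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        warnings.warn("constant covariate: falling back to the unadjusted mixed ANOVA")
        return mixed_anova_2x2(data, subject, between, within, value)

    plain = mixed_anova_2x2(data, subject, between, within, value)
    m = df[within].nunique()
    y = subj_means.to_numpy(dtype=float)
    groups = df.groupby(subject)[between].first().loc[subj_means.index]
    g_ind = (groups == sorted(groups.unique())[1]).to_numpy(dtype=float)
    ones = np.ones_like(y)
    sse_full = _ols_sse(np.column_stack([ones, x, g_ind]), y)
    sse_reduced = _ols_sse(np.column_stack([ones, x]), y)
    ss_group = max(sse_reduced - sse_full, 0.0) * m  # observation scale
    ss_error = sse_full * m
    n_subjects = y.size
    between_res = _f_result(
        ss_group, 1.0, ss_error, float(n_subjects - 3), "mixed-ancova between"
    )
    return {
        "between": between_res,
        "within": plain["within"],
        "interaction": plain["interaction"],
    }


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power setup for the within-between interaction F-test."""

    f: float = 0.2
    alpha: float = 0.05
    target_power: float = 0.90
    groups: int = 2
    measurements: int = 2
    rho: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("effect size f must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.target_power < 1:
            raise ValueError("alpha and target_power must lie in (0, 1)")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")
        if self.measurements < 2 or self.groups < 2:
            raise ValueError("need at least 2 groups and 2 measurements")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")


def power_within_between(n_total: int, spec: PowerSpec) -> float:
    """Power of the groups × measurements interaction test at total N.

    Noncentral-F exceedance of the α critical value with
    df₁ = (g−1)(m−1), df₂ = (N−g)(m−1)ε and noncentrality
    λ = f²·N·(m·ε)/(1−ρ); repeated measurements boost the effective
    effect through their correlation ρ.
    """
    g, m, eps = spec.groups, spec.measurements, spec.epsilon
    df1 = (g - 1) * (m - 1) * eps
    df2 = (n_total - g) * (m - 1) * eps
    if df2 <= 0:
        return 0.0
    lam = spec.f**2 * n_total * (m * eps) / (1 - spec.rho)
    crit = sps.f.isf(spec.alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def power_min_n(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest total sample size reaching the target power."""
    n = spec.groups + 1
    while (n - spec.groups) * (spec.measurements - 1) * spec.epsilon < 1:
        n += 1
    while n <= n_max:
        if power_within_between(n, spec) >= spec.target_power:
            return n
        n += 1
    raise ValueError(f"target power not reachable within N <= {n_max}")
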