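"""Group-comparison statistics for tract profiles and summary tables.

Implements the one-way tests used pointwise along 100-node tract profiles:

* classic one-way ANOVA (equal-variance F = MS_between / MS_within),
* Welch's heteroscedastic ANOVA (precision weights w_i = n_i / s_i^2,
  weighted grand mean, Satterthwaite-type denominator df),
* the Brown–Forsythe means test
  F* = Σ n_i (x̄_i − x̄)² / Σ (1 − n_i/N) s_i²  with Satterthwaite df,

plus the same classic ANOVA computable from printed (n, mean, sd) group
summaries, Pearson's χ² test of independence for count tables, linear
age/sex residualization, post hoc pairwise t-tests, and the rule that
drops tracts whose tracking-failure fraction is too high.

All tests return ``(statistic, (df1, df2), p)``; p-values are upper-tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Size, mean and standard deviation of one group — a demographics-table
    row entry, sufficient for the classic F test."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _check_groups(groups, need_var: bool = False):
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=float)
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if need_var and a.var(ddof=1) <= 0:
            raise ValueError(f"group {i} has zero within-group variance")
        out.append(a)
    return out


def anova_oneway(groups):
    """Classic one-way ANOVA F test.

    F = MS_between / MS_within with df (k−1, N−k), assuming equal group
    variances.  Returns ``(F, (df1, df2), p)``.
    """
    groups = _check_groups(groups)
    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    N = ns.sum()
    grand = np.concatenate(groups).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df1, df2 = k - 1, N - k
    if ss_within == 0.0:
        F = 0.0 if ss_between == 0.0 else np.inf
    else:
        F = (ss_between / df1) / (ss_within / df2)
    return F, (df1, int(df2)), float(stats.f.sf(F, df1, df2))


def anova_from_summaries(summaries):
    """Classic one-way ANOVA from (n, mean, sd) group summaries.

    Algebraically identical to :func:`anova_oneway` on raw data with these
    summaries: SS_between from sizes and means, SS_within = Σ (n_i−1) sd_i².
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    k = len(summaries)
    N = ns.sum()
    grand = (ns * means).sum() / N
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds ** 2).sum())
    df1, df2 = k - 1, N - k
    if ss_within == 0.0:
        F = 0.0 if ss_between == 0.0 else np.inf
    else:
        F = (ss_between / df1) / (ss_within / df2)
    return F, (df1, int(df2)), float(stats.f.sf(F, df1, df2))


def welch_anova(groups):
    """Welch's heteroscedastic one-way test.

    Weights w_i = n_i / s_i²; statistic
    ``W = [Σ w_i (x̄_i − x̃)² / (k−1)] / [1 + 2(k−2)/(k²−1) Λ]`` with
    ``Λ = Σ (1 − w_i/u)² / (n_i − 1)``, u = Σ w_i, x̃ the weighted grand
    mean; denominator df = (k²−1) / (3Λ).  Requires positive within-group
    variances.
    """
    groups = _check_groups(groups, need_var=True)
    k = len(groups)
    ns = np.array([g.size for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    variances = np.array([g.var(ddof=1) for g in groups])
    w = ns / variances
    u = w.sum()
    tilde = (w * means).sum() / u
    lam = float((((1 - w / u) ** 2) / (ns - 1)).sum())
    num = float((w * (means - tilde) ** 2).sum()) / (k - 1)
    den = 1 + 2 * (k - 2) / (k ** 2 - 1) * lam
    W = num / den
    df1 = k - 1
    df2 = (k ** 2 - 1) / (3 * lam)
    return W, (df1, float(df2)), float(stats.f.sf(W, df1, df2))


def brown_forsythe(groups):
    """Brown–Forsythe test of equal means with unequal variances.

    F* = Σ n_i (x̄_i − x̄)² / Σ (1 − n_i/N) s_i², referred to an F
    distribution with k−1 and Satterthwaite df
    ``1/f = Σ c_i² / (n_i − 1)`` where
    ``c_i = (1 − n_i/N) s_i² / Σ_j (1 − n_j/N) s_j²``.
    """
    groups = _check_groups(groups, need_var=True)
    k = len(groups)
    ns = np.array([g.size for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    variances = np.array([g.var(ddof=1) for g in groups])
    N = ns.sum()
    grand = np.concatenate(groups).mean()
    num = float((ns * (means - grand) ** 2).sum())
    denom_terms = (1 - ns / N) * variances
    den = float(denom_terms.sum())
    Fstar = num / den
    c = denom_terms / den
    df2 = 1.0 / float((c ** 2 / (ns - 1)).sum())
    df1 = k - 1
    return Fstar, (df1, float(df2)), float(stats.f.sf(Fstar, df1, df2))


_TESTS = {"anova": anova_oneway, "welch": welch_anova, "brown_forsythe": brown_forsythe}


def chi_square_independence(table):
    """Pearson χ² test of independence on an r×c count table, no continuity
    correction; df = (r−1)(c−1)."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or np.any(table < 0):
            raise ValueError("counts must be nonnegative integers")
        table = np.round(table).astype(int)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def adjust_covariates(values, age, sex):
    """Residualize values on [1, age, sex] by OLS, re-centered to the
    grand mean — removes linear age/sex effects before group testing."""
    y = np.asarray(values, dtype=float)
    X = np.column_stack([np.ones_like(y), np.asarray(age, float),
                         np.asarray(sex, float)])
    if X.shape[0] != y.shape[0]:
        raise ValueError("covariate rows do not align with values")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("covariate design is rank-deficient")
    resid = y - X @ coef
    return resid + y.mean()


class TractExcludedError(ValueError):
    """Requested analysis on a tract dropped by the exclusion rule."""


def exclude_untrackable_tracts(profiles, max_failure_fraction: float = 0.25):
    """Drop tracts whose tracking-failure fraction exceeds the threshold.

    Returns ``(retained_tracts, report)`` where the report is a DataFrame
    with per-tract failure counts, fractions and the retained flag.
    """
    counts = profiles.failure_counts()
    n = profiles.n_subjects
    frac = counts / n
    retained = [t for t in profiles.tracts if frac[t] <= max_failure_fraction]
    report = pd.DataFrame({
        "tract": list(profiles.tracts),
        "n_failures": counts.values,
        "n_subjects": n,
        "failure_fraction": frac.values,
        "retained": [t in retained for t in profiles.tracts],
    })
    return retained, report


def _tract_groups(profiles, tract: str, metric: str):
    """Tracked subjects' node arrays split by group, with age/sex."""
    j = profiles.tract_index(tract)
    mask = profiles.tracked[:, j]
    arr = profiles.metric_array(metric)[mask, j, :]
    groups = profiles.group[mask]
    age = profiles.age[mask]
    sex = profiles.sex[mask]
    return arr, groups, age, sex


def pointwise_profile_test(profiles, metric: str, tract: str, test: str = "anova",
                           alpha: float = 0.05, adjust: bool = True,
                           fdr: bool = False,
                           max_failure_fraction: float | None = 0.25) -> pd.DataFrame:
    """Node-by-node group comparison along one tract profile.

    Untracked subjects are excluded; values are age/sex-residualized per
    node when `adjust` is set; significance is raw p < alpha by default,
    or Benjamini–Hochberg across the tract's nodes when `fdr` is set.

    Returns a DataFrame with one row per node: statistic, df1, df2, p,
    significant.  Raises :class:`TractExcludedError` when the tract fails
    the tracking-failure rule (pass ``max_failure_fraction=None`` to skip
    the gate).
    """
    if test not in _TESTS:
        raise ValueError(f"test must be one of {sorted(_TESTS)}")
    if max_failure_fraction is not None:
        retained, _ = exclude_untrackable_tracts(profiles, max_failure_fraction)
        if tract not in retained:
            raise TractExcludedError(
                f"tract {tract!r} excluded: tracking-failure fraction exceeds "
                f"{max_failure_fraction}")
    arr, groups, age, sex = _tract_groups(profiles, tract, metric)
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups among tracked subjects")
    fn = _TESTS[test]
    rows = []
    for node in range(arr.shape[1]):
        vals = arr[:, node]
        if adjust:
            vals = adjust_covariates(vals, age, sex)
        stat, (df1, df2), p = fn([vals[groups == g] for g in labels])
        rows.append((node, stat, df1, df2, p))
    out = pd.DataFrame(rows, columns=["node", "statistic", "df1", "df2", "p"])
    if fdr:
        out["significant"] = _benjamini_hochberg(out["p"].to_numpy(), alpha)
    else:
        out["significant"] = out["p"] < alpha
    return out


def _benjamini_hochberg(pvals: np.ndarray, alpha: float) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = pvals[order] <= thresh
    keep = np.zeros(m, dtype=bool)
    if passed.any():
        keep[order[: np.flatnonzero(passed).max() + 1]] = True
    return keep


def posthoc_pairwise(profiles, tract: str, metric: str, node_range,
                     adjust: bool = True) -> pd.DataFrame:
    """Two-sided two-sample t-tests per group pair on node-averaged,
    optionally age/sex-adjusted values over an inclusive node range.

    Pairs where either group has fewer than 2 tracked subjects are skipped
    with a warning row (p = NaN).
    """
    import warnings

    arr, groups, age, sex = _tract_groups(profiles, tract, metric)
    lo, hi = node_range
    vals = arr[:, lo:hi + 1].mean(axis=1)
    if adjust:
        vals = adjust_covariates(vals, age, sex)
    labels = list(dict.fromkeys(groups))
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = vals[groups == labels[i]], vals[groups == labels[j]]
            if a.size < 2 or b.size < 2:
                warnings.warn(f"pair ({labels[i]}, {labels[j]}) skipped: "
                              "fewer than 2 tracked subjects", stacklevel=2)
                rows.append((labels[i], labels[j], np.nan, np.nan))
                continue
            t, p = stats.ttest_ind(a, b)
            rows.append((labels[i], labels[j], float(t), float(p)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p"])
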