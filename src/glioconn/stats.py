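"""Inferential machinery for the group and coherence analyses.

One-way MANOVA with Pillai's trace ``V = tr(H (H + E)^-1)`` and its standard
F approximation, classical one-way ANOVA, Bonferroni-adjusted pairwise
post-hoc t-tests on the pooled ANOVA error term, Pearson partial correlation
via least-squares residualization, the Pearson chi-square independence test,
and Bonferroni family thresholds.

For the Pillai approximation, with g groups, p dependent variables and N
observations, let s = min(p, g-1), m = (|p - g + 1| - 1)/2 and
n = (N - g - p - 1)/2; then

    F = (2n + s + 1) / (2m + s + 1) * V / (s - V)

is approximately F-distributed with df1 = s(2m + s + 1) and
df2 = s(2n + s + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.stats

__all__ = [
    "ManovaResult", "AnovaResult", "PosthocResult", "PartialCorrResult",
    "ChiSquareResult", "manova_pillai", "anova_oneway", "posthoc_bonferroni",
    "partial_correlation", "partial_corr_significance",
    "chi_square_independence", "bonferroni_threshold", "StatsError",
]


class StatsError(ValueError):
    """Raised for invalid statistical inputs (rank deficiency, sizes, ...)."""


@dataclass(frozen=True)
class ManovaResult:
    pillai_V: float
    F: float
    df1: int
    df2: int
    p: float
    groups: tuple
    n_per_group: tuple
    wilks_lambda: float  # secondary statistic, clearly labelled


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class PosthocResult:
    group_a: str
    group_b: str
    mean_difference: float
    t: float
    df: int
    p_raw: float
    p_bonferroni: float


@dataclass(frozen=True)
class PartialCorrResult:
    r_partial: float
    df: int
    t: float
    p_two_sided: float
    covariates: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float


def _group_split(group_labels, y: np.ndarray):
    labels = np.asarray(group_labels)
    order = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    groups = [y[labels == g] for g in order]
    return order, groups


def manova_pillai(group_labels, dv_matrix) -> ManovaResult:
    """One-way MANOVA, Pillai's trace with the standard F approximation."""
    y = np.asarray(dv_matrix, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if np.isnan(y).any():
        raise StatsError("dependent variables contain missing values")
    labels, groups = _group_split(group_labels, y)
    g = len(labels)
    if g < 2:
        raise StatsError("MANOVA needs at least two groups")
    n_total, p = y.shape
    for lab, arr in zip(labels, groups):
        if len(arr) < p + 1:
            raise StatsError(
                f"group {lab!r} has {len(arr)} members; needs >= {p + 1}")
    grand = y.mean(axis=0)
    h = np.zeros((p, p))
    e = np.zeros((p, p))
    for arr in groups:
        gm = arr.mean(axis=0)
        d = (gm - grand)[:, None]
        h += len(arr) * (d @ d.T)
        c = arr - gm
        e += c.T @ c
    t_mat = h + e
    if np.linalg.matrix_rank(e) < p:
        raise StatsError("within-group SSCP matrix is rank deficient; "
                         "dependent variables are collinear within groups")
    v = float(np.trace(np.linalg.solve(t_mat, h)))
    wilks = float(np.linalg.det(e) / np.linalg.det(t_mat))
    s = min(p, g - 1)
    m = (abs(p - (g - 1)) - 1) / 2.0
    n = (n_total - g - p - 1) / 2.0
    df1 = int(round(s * (2 * m + s + 1)))
    df2 = int(round(s * (2 * n + s + 1)))
    f_stat = ((2 * n + s + 1) / (2 * m + s + 1)) * v / (s - v)
    p_value = float(scipy.stats.f.sf(f_stat, df1, df2))
    return ManovaResult(pillai_V=v, F=float(f_stat), df1=df1, df2=df2,
                        p=p_value, groups=tuple(labels),
                        n_per_group=tuple(len(a) for a in groups),
                        wilks_lambda=wilks)


def anova_oneway(group_labels, dv) -> AnovaResult:
    """Classical one-way ANOVA; df1 = g - 1, df2 = N - g."""
    y = np.asarray(dv, dtype=float)
    labels, groups = _group_split(group_labels, y)
    g = len(labels)
    if g < 2:
        raise StatsError("ANOVA needs at least two groups")
    n_total = len(y)
    if n_total <= g:
        raise StatsError("ANOVA needs more observations than groups")
    f_stat, p_value = scipy.stats.f_oneway(*groups)
    return AnovaResult(F=float(f_stat), df1=g - 1, df2=n_total - g,
                       p=float(p_value))


def posthoc_bonferroni(group_labels, dv):
    """Pairwise t-tests on the pooled ANOVA error term, Bonferroni-adjusted.

    The pooled within-group variance (error df = N - g) is shared by all
    contrasts; two-sided raw p-values are multiplied by the number of pairs
    and capped at 1.
    """
    y = np.asarray(dv, dtype=float)
    labels, groups = _group_split(group_labels, y)
    g = len(labels)
    if g < 2:
        raise StatsError("post-hoc tests need at least two groups")
    n_total = len(y)
    df_error = n_total - g
    if df_error <= 0:
        raise StatsError("no error degrees of freedom")
    ssw = sum(((arr - arr.mean()) ** 2).sum() for arr in groups)
    mse = ssw / df_error
    if mse == 0:
        raise StatsError("zero pooled error variance")
    m = g * (g - 1) // 2
    results = []
    for (ia, ib) in combinations(range(g), 2):
        a, b = groups[ia], groups[ib]
        diff = a.mean() - b.mean()
        se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
        t = diff / se
        p_raw = float(2.0 * scipy.stats.t.sf(abs(t), df_error))
        results.append(PosthocResult(
            group_a=str(labels[ia]), group_b=str(labels[ib]),
            mean_difference=float(diff), t=float(t), df=df_error,
            p_raw=p_raw, p_bonferroni=min(1.0, m * p_raw)))
    return results


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(x, y, covariates=None,
                        covariate_names=()) -> PartialCorrResult:
    """Pearson partial correlation of x and y given covariates.

    Both variables are residualized on [1, covariates] by least squares; the
    Pearson correlation of the residuals is tested with
    t = r sqrt(df / (1 - r^2)), df = N - 2 - k, two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != n:
            raise StatsError("covariate rows must match x/y length")
    k = z.shape[1]
    if n < k + 4:
        raise StatsError(f"need at least {k + 4} observations for {k} "
                         f"covariate(s); got {n}")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise StatsError("covariates are rank deficient")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx = np.sqrt((rx ** 2).sum())
    sy = np.sqrt((ry ** 2).sum())
    tol_x = 1e-10 * max(1.0, float(np.abs(x).max()))
    tol_y = 1e-10 * max(1.0, float(np.abs(y).max()))
    if sx <= tol_x or sy <= tol_y:
        raise StatsError("zero residual variance; partial correlation "
                         "undefined")
    r = float((rx @ ry) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    return partial_corr_significance(r, n, k, covariate_names)


def partial_corr_significance(r: float, n: int, k: int = 1,
                              covariate_names=()) -> PartialCorrResult:
    """Significance of a partial correlation coefficient.

    df = n - 2 - k; t = r sqrt(df / (1 - r^2)); two-sided p from the t
    distribution.  Useful both internally and for checking reported (r, n)
    pairs.
    """
    df = n - 2 - k
    if df < 1:
        raise StatsError(f"non-positive degrees of freedom: {df}")
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return PartialCorrResult(r_partial=float(r), df=int(df), t=float(t),
                             p_two_sided=p,
                             covariates=tuple(covariate_names))


def chi_square_independence(table) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise StatsError("contingency table must be 2-D")
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise StatsError("contingency table must hold non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise StatsError("contingency table has an empty row or column")
    res = scipy.stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(chi2=float(res.statistic), df=int(res.dof),
                           p=float(res.pvalue))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m (report rounded to 3 decimals)."""
    if not 0 < alpha < 1:
        raise StatsError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise StatsError(f"family size must be >= 1, got {m}")
    return alpha / m
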