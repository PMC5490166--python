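"""Cohort statistics implemented from first principles.

Group comparisons with age adjustment (ANCOVA with a slope-equality
interaction check), classical pooled/Welch t-tests, Fisher's exact test,
one-way ANOVA with Dunnett contrasts against a reference group, partial
correlations adjusted for somatic growth (sex, height), the modified
inter-observer coefficient of variation, and Bland-Altman agreement.

Least-squares fits use the normal equations with an independent QR
cross-check; Dunnett adjusted p-values come from the equicorrelated
multivariate-t distribution by seeded Monte Carlo (default) or 1D numerical
integration.  All tests are two-sided at alpha = 0.05 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps
from scipy.linalg import solve_triangular

__all__ = [
    "AdjustedComparison",
    "AdjustedAssociation",
    "AgreementResult",
    "CoVResult",
    "DunnettResult",
    "compare_groups_ancova",
    "student_t_two_sample",
    "fisher_exact_2x2",
    "anova_dunnett",
    "adjusted_association",
    "cov_interobserver",
    "bland_altman",
    "percent_group_difference",
]

ALPHA = 0.05


# ---------------------------------------------------------------- regression


def _ols(X: np.ndarray, y: np.ndarray, names: Sequence[str]):
    """OLS by normal equations, cross-checked against a QR solve.

    Returns (beta, cov_beta, dof, residuals).  Raises on rank deficiency,
    naming the collinear columns.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = np.linalg.norm(X, axis=0)
    bad = diag <= 1e-10 * np.maximum(scale, 1.0)
    if bad.any():
        cols = [names[i] for i in np.nonzero(bad)[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {cols}")
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    beta_qr = solve_triangular(R, Q.T @ y)
    denom = np.maximum(np.abs(beta_qr), 1.0)
    if np.max(np.abs(beta - beta_qr) / denom) > 1e-6:
        raise ArithmeticError("normal-equation and QR solutions disagree")
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(xtx)
    return beta, cov, dof, resid


def _t_pvalue(t: float, dof: int) -> float:
    return float(2.0 * sps.t.sf(abs(t), dof))


def _drop_missing(df: pd.DataFrame, cols: Sequence[str]) -> Tuple[pd.DataFrame, int]:
    sub = df[list(cols)]
    kept = sub.dropna()
    return kept, len(sub) - len(kept)


def _encode(series: pd.Series) -> np.ndarray:
    """Numeric passthrough; binary categoricals coded 0/1 by sorted level."""
    if pd.api.types.is_numeric_dtype(series):
        return series.to_numpy(float)
    levels = sorted(series.dropna().unique())
    if len(levels) > 2:
        raise ValueError(f"cannot encode {series.name!r}: more than two levels")
    mapping = {lev: i for i, lev in enumerate(levels)}
    return series.map(mapping).to_numpy(float)


# ------------------------------------------------------------------- ANCOVA


@dataclass
class AdjustedComparison:
    """Covariate-adjusted two-group difference.

    ``difference``/``se``/``p`` come from the additive (no-interaction)
    model.  ``interaction_p`` tests slope equality; when it is significant
    (``slopes_differ``), a single adjusted difference is ill-defined and
    ``difference_at_mean_covariate`` (the interaction-model contrast at the
    overall covariate mean) should be quoted alongside.
    """

    outcome: str
    difference: float  # second sorted group level minus the first
    se: float
    p: float
    covariates: Tuple[str, ...]
    interaction_p: float
    group_levels: Tuple[str, str]
    n_used: int
    n_dropped: int
    slopes_differ: bool = False
    difference_at_mean_covariate: float = float("nan")
    se_at_mean_covariate: float = float("nan")


def compare_groups_ancova(
    df: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    covariate: str = "age",
    alpha: float = ALPHA,
) -> AdjustedComparison:
    """ANCOVA: outcome ~ group + covariate, with a slope-equality check.

    The group difference (second sorted level minus the first), its SE and
    p always come from the additive model, keeping the test at its nominal
    level; the interaction model's slope-equality p and its contrast at the
    overall covariate mean are reported alongside for the case where the
    slopes differ.  Missing rows are deleted listwise and counted.
    """
    data, n_dropped = _drop_missing(df, [outcome, group_col, covariate])
    levels = sorted(data[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {levels}")
    for lev in levels:
        if (data[group_col] == lev).sum() < 3:
            raise ValueError(f"group {lev!r} has fewer than 3 observations")
    g = (data[group_col] == levels[1]).to_numpy(float)
    z = data[covariate].to_numpy(float)
    y = data[outcome].to_numpy(float)
    n = len(y)
    ones = np.ones(n)

    X0 = np.column_stack([ones, g, z])
    beta0, cov0, dof0, _ = _ols(X0, y, ["intercept", group_col, covariate])
    X1 = np.column_stack([ones, g, z, g * z])
    beta1, cov1, dof1, _ = _ols(
        X1, y, ["intercept", group_col, covariate, f"{group_col}:{covariate}"]
    )
    # degenerate (numerically exact) fits give a 0/0 interaction statistic
    y_scale = float(np.sqrt(np.mean(y**2))) or 1.0
    se_int = np.sqrt(max(cov1[3, 3], 0.0))
    if se_int <= 1e-10 * y_scale:
        p_int = 1.0 if abs(beta1[3]) <= 1e-8 * y_scale else 0.0
    else:
        p_int = _t_pvalue(beta1[3] / se_int, dof1)

    diff = float(beta0[1])
    se = float(np.sqrt(max(cov0[1, 1], 0.0)))
    p = _t_pvalue(diff / se, dof0) if se > 0 else (1.0 if diff == 0 else 0.0)
    # interaction-model contrast at the overall covariate mean (quoted when
    # the slopes differ; computed unconditionally so it carries no selection)
    zbar = float(z.mean())
    diff_at_mean = float(beta1[1] + zbar * beta1[3])
    var_at_mean = cov1[1, 1] + zbar**2 * cov1[3, 3] + 2 * zbar * cov1[1, 3]
    return AdjustedComparison(
        outcome=outcome,
        difference=diff,
        se=se,
        p=p,
        covariates=(covariate,),
        interaction_p=p_int,
        group_levels=(levels[0], levels[1]),
        n_used=n,
        n_dropped=n_dropped,
        slopes_differ=bool(p_int < alpha),
        difference_at_mean_covariate=diff_at_mean,
        se_at_mean_covariate=float(np.sqrt(max(var_at_mean, 0.0))),
    )


# ------------------------------------------------------------------ t-tests


def student_t_two_sample(
    df: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    welch: bool = False,
) -> Tuple[float, float, float]:
    """Two-sample t-test: returns (difference, t, two-sided p).

    Pooled-variance by default (Welch optional); the difference is the
    second sorted group level minus the first.
    """
    data, _ = _drop_missing(df, [outcome, group_col])
    levels = sorted(data[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {levels}")
    a = data.loc[data[group_col] == levels[1], outcome].to_numpy(float)
    b = data.loc[data[group_col] == levels[0], outcome].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / len(a) + vb / len(b)
        dof = se2**2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        ) if se2 > 0 else 1.0
    else:
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
        se2 = sp2 * (1.0 / len(a) + 1.0 / len(b))
        dof = len(a) + len(b) - 2
    se = np.sqrt(se2)
    if se == 0:
        return diff, 0.0, 1.0 if diff == 0 else 0.0
    t = diff / se
    return diff, float(t), _t_pvalue(t, dof)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities not
    exceeding that of the observed table."""
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
            raise ValueError("counts must be non-negative integers")
        tab = np.round(tab).astype(int)
    a, b = int(tab[0, 0]), int(tab[0, 1])
    c, d = int(tab[1, 0]), int(tab[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    kmin, kmax = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = sps.hypergeom.pmf(ks, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


# ------------------------------------------------------------------ Dunnett


@dataclass
class DunnettContrast:
    group: str
    estimate: float
    t: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class DunnettResult:
    f_statistic: float
    f_p: float
    reference: str
    contrasts: list
    dof: int
    method: str


def _dunnett_p_mc(t_obs: np.ndarray, lambdas: np.ndarray, dof: int, n_mc: int, seed: int):
    rng = np.random.default_rng(seed)
    k = len(lambdas)
    z0 = rng.standard_normal(n_mc)
    eps = rng.standard_normal((n_mc, k))
    z = lambdas * z0[:, None] + np.sqrt(1.0 - lambdas**2) * eps
    s = np.sqrt(rng.chisquare(dof, n_mc) / dof)
    m = np.abs(z / s[:, None]).max(axis=1)
    return np.array([float(np.mean(m >= abs(t))) for t in t_obs])


def _dunnett_p_integration(t_obs: np.ndarray, lambdas: np.ndarray, dof: int):
    """P(max_i |T_i| >= t) for the equicorrelated-factor multivariate t."""
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(96)
    gh_w = gh_w / np.sqrt(2.0 * np.pi)
    sqrt1m = np.sqrt(1.0 - lambdas**2)

    def cdf_max(t):
        def inner(s):
            # s: scalar scale factor sqrt(chi2_nu / nu)
            upper = (t * s - np.outer(gh_x, lambdas)) / sqrt1m
            lower = (-t * s - np.outer(gh_x, lambdas)) / sqrt1m
            probs = np.prod(sps.norm.cdf(upper) - sps.norm.cdf(lower), axis=1)
            return float(gh_w @ probs)

        # density of s: chi_nu scaled by 1/sqrt(nu)
        def integrand(s):
            return inner(s) * sps.chi.pdf(s * np.sqrt(dof), dof) * np.sqrt(dof)

        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
        return val

    return np.array([1.0 - cdf_max(abs(t)) for t in t_obs])


def anova_dunnett(
    df: pd.DataFrame,
    outcome: str,
    class_col: str = "remodeling_class",
    reference: str = "normal_geometry",
    merge: Iterable[str] = ("concentric_remodeling", "eccentric_hypertrophy"),
    method: str = "mc",
    n_mc: int = 200_000,
    seed: int = 0,
) -> DunnettResult:
    """One-way ANOVA plus Dunnett contrasts against a reference group.

    Groups listed in ``merge`` are pooled into one category before testing
    (small-sample pooling of the intermediate remodeling classes).  Adjusted
    two-sided p-values come from the multivariate-t max-|T| distribution
    with factor correlations ``lambda_i = sqrt(n_i / (n_i + n_ref))``, by
    seeded Monte Carlo (``method="mc"``, default) or numerical integration
    (``method="integration"``).  Adjusted p is never reported below the
    unadjusted p.
    """
    data, _ = _drop_missing(df, [outcome, class_col])
    merge = set(merge)
    merged_name = "+".join(sorted(merge))

    def relabel(c):
        return merged_name if c in merge else c

    labels = data[class_col].map(relabel)
    if reference not in set(labels):
        raise ValueError(f"reference class {reference!r} missing from the data")
    groups = [g for g in sorted(labels.unique()) if g != reference]
    if not groups:
        raise ValueError("no comparison groups after merging")
    y_ref = data.loc[labels == reference, outcome].to_numpy(float)
    if len(y_ref) < 3:
        raise ValueError("reference group needs n >= 3")

    ys = {g: data.loc[labels == g, outcome].to_numpy(float) for g in groups}
    all_groups = [y_ref] + [ys[g] for g in groups]
    N = sum(len(y) for y in all_groups)
    k_total = len(all_groups)
    grand = np.concatenate(all_groups).mean()
    ssb = sum(len(y) * (y.mean() - grand) ** 2 for y in all_groups)
    ssw = sum(((y - y.mean()) ** 2).sum() for y in all_groups)
    dof = N - k_total
    if dof <= 0:
        raise ValueError("not enough observations for ANOVA")
    msw = ssw / dof
    f_stat = (ssb / (k_total - 1)) / msw if msw > 0 else np.inf
    f_p = float(sps.f.sf(f_stat, k_total - 1, dof)) if np.isfinite(f_stat) else 0.0

    n_ref = len(y_ref)
    est = np.array([ys[g].mean() - y_ref.mean() for g in groups])
    se = np.sqrt(msw * (1.0 / np.array([len(ys[g]) for g in groups]) + 1.0 / n_ref))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
    lambdas = np.sqrt(
        np.array([len(ys[g]) for g in groups])
        / (np.array([len(ys[g]) for g in groups]) + n_ref)
    )
    p_unadj = np.array([_t_pvalue(t, dof) if np.isfinite(t) else 0.0 for t in t_obs])
    finite = np.isfinite(t_obs)
    p_adj = np.zeros_like(p_unadj)
    if finite.any():
        if method == "mc":
            p_adj[finite] = _dunnett_p_mc(t_obs[finite], lambdas, dof, n_mc, seed)
        elif method == "integration":
            p_adj[finite] = _dunnett_p_integration(t_obs[finite], lambdas, dof)
        else:
            raise ValueError(f"unknown method {method!r}")
    p_adj = np.maximum(p_adj, p_unadj)  # adjusted never below unadjusted
    contrasts = [
        DunnettContrast(g, float(e), float(t), float(pu), float(pa))
        for g, e, t, pu, pa in zip(groups, est, t_obs, p_unadj, p_adj)
    ]
    return DunnettResult(
        f_statistic=float(f_stat),
        f_p=f_p,
        reference=reference,
        contrasts=contrasts,
        dof=dof,
        method=method,
    )


# ----------------------------------------------------------- partial correl


@dataclass
class AdjustedAssociation:
    outcome: str
    predictor: str
    r: float
    p: float
    covariates: Tuple[str, ...]
    n: int


def adjusted_association(
    df: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: Sequence[str] = ("sex", "height"),
) -> AdjustedAssociation:
    """Partial correlation of outcome and predictor given covariates.

    Both variables are residualised on the covariates (with intercept); the
    Pearson correlation of the residuals is reported with its t-based
    two-sided p on ``n - k - 2`` degrees of freedom.  With no covariates
    this reduces to the ordinary Pearson correlation.
    """
    cols = [outcome, predictor, *covariates]
    data, _ = _drop_missing(df, cols)
    n = len(data)
    k = len(covariates)
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} complete rows, have {n}")
    y = _encode(data[outcome])
    x = _encode(data[predictor])
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    if np.ptp(y) == 0:
        raise ValueError(f"outcome {outcome!r} is constant")
    Z = np.column_stack(
        [np.ones(n)] + [_encode(data[c]) for c in covariates]
    )
    names = ["intercept", *covariates]
    _, _, _, ry = _ols(Z, y, names)
    _, _, _, rx = _ols(Z, x, names)
    denom = np.sqrt(float(ry @ ry) * float(rx @ rx))
    if denom == 0:
        raise ValueError("residual variance is zero after adjustment")
    r = float((ry @ rx) / denom)
    r = float(np.clip(r, -1.0, 1.0))
    dof = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r**2))
        p = _t_pvalue(t, dof)
    return AdjustedAssociation(outcome, predictor, r, p, tuple(covariates), n)


# ----------------------------------------------------------- reproducibility


@dataclass
class CoVResult:
    """Modified inter-observer coefficient of variation.

    ``cov_pct = 100 * sum_i SD(x1_i, x2_i) / |sum_i mean(x1_i, x2_i)|``,
    where the two-value sample SD equals ``|x1 - x2| / sqrt(2)``.  A value
    within 20% is flagged reproducible.
    """

    cov_pct: float
    reproducible: bool
    n_pairs: int
    threshold_pct: float = 20.0


def cov_interobserver(x1, x2, threshold_pct: float = 20.0) -> CoVResult:
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if x1.shape != x2.shape or x1.ndim != 1 or len(x1) < 1:
        raise ValueError("need matching 1D observer arrays with >= 1 pair")
    numerator = float(np.sum(np.abs(x1 - x2) / np.sqrt(2.0)))
    denominator = float(abs(np.sum((x1 + x2) / 2.0)))
    if denominator == 0:
        raise ValueError("sum of pair means is zero; CoV undefined")
    cov_pct = 100.0 * numerator / denominator
    return CoVResult(cov_pct, cov_pct <= threshold_pct, len(x1), threshold_pct)


@dataclass
class AgreementResult:
    """Bland-Altman bias and 95% limits of agreement (x2 - x1)."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    n_pairs: int


def bland_altman(x1, x2) -> AgreementResult:
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if x1.shape != x2.shape or x1.ndim != 1 or len(x1) < 2:
        raise ValueError("need matching 1D observer arrays with >= 2 pairs")
    d = x2 - x1
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd, len(d))


def percent_group_difference(mean_a: float, mean_b: float, rounded: bool = True):
    """Relative group difference ``100 (a - b) / b``, in percent.

    Rounded to the nearest integer for reporting by default.
    """
    if mean_b == 0:
        raise ValueError("reference mean must be non-zero")
    pct = 100.0 * (mean_a - mean_b) / mean_b
    return int(round(pct)) if rounded else float(pct)
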