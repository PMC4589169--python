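"""Statistical battery for the cohort stage.

Implements the analysis conventions of a typical SPSS-era neuropathology
study: Shapiro-Wilk normality routing between parametric (pooled-variance
two-sample t) and non-parametric (Mann-Whitney U) group contrasts,
age-controlled partial Spearman/Pearson correlations with one-tailed
p-values, a Pearson chi-square for 2x2 tables, and forward stepwise linear
regression with p-value entry/removal.

Partial Spearman is computed as partial Pearson on midranks with the
covariates ranked as well, matching the common implementation.  The
stepwise driver reports standardized coefficients, model R^2 and F, and
the would-be statistics of excluded candidates at the final step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "StepwiseModel",
    "pooled_t",
    "pooled_t_from_samples",
    "mann_whitney_u",
    "partial_corr",
    "stepwise_forward",
    "route_test",
    "chi_square_2x2",
]


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    method: str
    controlled: tuple[str, ...]
    n: int
    df: int
    p_one_tailed: float
    p_two_tailed: float
    tails: int


@dataclass(frozen=True)
class StepwiseModel:
    dependent: str
    candidates: tuple[str, ...]
    selected: tuple[str, ...]          # in entry order
    beta_std: dict[str, float]         # standardized coefficients of selected
    p_values: dict[str, float]         # per selected predictor
    r_squared: float
    f_statistic: float
    f_pvalue: float
    n: int
    excluded: dict[str, tuple[float, float]]  # candidate -> (beta-in, p-in)


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (t, df, p_two_tailed) with df = n1 + n2 - 2.  Works directly from
    published group means/SDs/ns, so printed table rows can be re-derived.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def pooled_t_from_samples(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Pooled-variance t from raw samples (equal-variance independent t)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), int(x.size + y.size - 2), float(res.pvalue)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with midrank tie handling; U = min(U1, U2).

    The p-value uses exact enumeration for small, tie-free samples
    (n1*n2 <= 400) and the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    n1, n2 = x.size, y.size
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    method = "exact" if (n1 * n2 <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u2 = n1 * n2 - u1
    return float(min(u1, u2)), float(res.pvalue)


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """OLS residuals of v on [1, z]."""
    design = np.column_stack([np.ones(len(v)), z])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_corr(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[Mapping[str, Sequence[float]] | np.ndarray] = None,
    method: Literal["pearson", "spearman"] = "pearson",
    tails: int = 2,
    alternative: Literal["greater", "less"] = "greater",
) -> CorrelationResult:
    """(Partial) correlation of x and y, optionally controlling covariates.

    Pearson variant: correlation of the OLS residuals of x and y on the
    covariates.  Spearman variant: the same after midrank-transforming x, y
    and every covariate.  p from t = r*sqrt(df/(1-r^2)) with
    df = n - 2 - (number of covariates); one-tailed p is directional
    (default: positive association).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    cov_names: tuple[str, ...] = ()
    if covariates is None:
        z = np.empty((n, 0))
    elif isinstance(covariates, Mapping):
        cov_names = tuple(covariates)
        z = np.column_stack([np.asarray(covariates[k], dtype=float) for k in covariates])
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        cov_names = tuple(f"cov{i}" for i in range(z.shape[1]))
    k = z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} observations for {k} covariates")
    if method == "spearman":
        x = _rank(x)
        y = _rank(y)
        z = np.column_stack([_rank(z[:, j]) for j in range(k)]) if k else z
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input (possibly after ranking)")
    if k:
        xr = _residualize(x, z)
        yr = _residualize(y, z)
    else:
        xr, yr = x - x.mean(), y - y.mean()
    denom = np.sqrt((xr @ xr) * (yr @ yr))
    if denom == 0:
        raise ValueError("zero residual variance after controlling covariates")
    r = float(np.clip((xr @ yr) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
    p_two = 2.0 * stats.t.sf(abs(t), df)
    if alternative == "greater":
        p_one = stats.t.sf(t, df)
    else:
        p_one = stats.t.cdf(t, df)
    label = ("partial_" if k else "") + method
    return CorrelationResult(
        coefficient=r, method=label, controlled=cov_names, n=n, df=df,
        p_one_tailed=float(p_one), p_two_tailed=float(p_two), tails=tails,
    )


def _check_collinearity(X: pd.DataFrame, tol: float = 1e8) -> None:
    Xc = X.to_numpy(dtype=float)
    Xc = (Xc - Xc.mean(0)) / np.where(Xc.std(0) == 0, 1.0, Xc.std(0))
    cond = np.linalg.cond(Xc)
    if cond > tol:
        corr = np.corrcoef(Xc, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"collinear candidates (condition number {cond:.3g}): "
            f"'{X.columns[i]}' and '{X.columns[j]}'"
        )


def stepwise_forward(
    y: Sequence[float] | pd.Series,
    candidates: pd.DataFrame,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    dependent_name: str = "y",
) -> StepwiseModel:
    """Forward stepwise OLS with p-value entry and removal.

    At each step the excluded candidate with the smallest entry p-value below
    ``entry_p`` is added; after each addition, any included predictor whose
    p-value exceeds ``removal_p`` is removed; iteration stops when neither
    rule fires.  All variables are z-scored, so the reported coefficients are
    standardized betas.  Excluded-candidate statistics (beta and p were it
    entered into the final model) are reported alongside.
    """
    import statsmodels.api as sm

    if not entry_p < removal_p:
        raise ValueError("entry_p must be below removal_p")
    X = candidates.copy()
    yv = np.asarray(y, dtype=float)
    if X.isna().any().any() or np.isnan(yv).any():
        raise ValueError("stepwise regression requires complete cases")
    n = len(yv)
    _check_collinearity(X)

    # standardize everything -> standardized betas
    ystd = yv.std(ddof=0)
    if ystd == 0:
        raise ValueError("dependent variable is constant")
    yz = (yv - yv.mean()) / ystd
    Xz = (X - X.mean()) / X.std(ddof=0)

    def fit(names: Sequence[str]):
        design = sm.add_constant(Xz[list(names)].to_numpy(), has_constant="add")
        return sm.OLS(yz, design).fit()

    selected: list[str] = []
    while True:
        changed = False
        remaining = [c for c in X.columns if c not in selected]
        # entry step (skipped once the current model is numerically perfect:
        # entry p-values on a zero-variance residual are meaningless)
        saturated = bool(selected) and fit(selected).rsquared > 1.0 - 1e-12
        best_name, best_p = None, np.inf
        if not saturated:
            for name in remaining:
                res = fit(selected + [name])
                p = res.pvalues[-1]
                if p < best_p:
                    best_name, best_p = name, p
        if best_name is not None and best_p < entry_p:
            selected.append(best_name)
            changed = True
        # removal step
        if selected:
            res = fit(selected)
            pvals = dict(zip(selected, res.pvalues[1:]))
            worst = max(pvals, key=pvals.get)
            if pvals[worst] > removal_p:
                selected.remove(worst)
                changed = True
        if not changed:
            break

    if selected:
        res = fit(selected)
        beta = dict(zip(selected, (float(b) for b in res.params[1:])))
        pv = dict(zip(selected, (float(p) for p in res.pvalues[1:])))
        r2 = float(res.rsquared)
        fstat = float(res.fvalue)
        fp = float(res.f_pvalue)
    else:
        beta, pv, r2, fstat, fp = {}, {}, 0.0, float("nan"), float("nan")
    excluded: dict[str, tuple[float, float]] = {}
    for name in X.columns:
        if name in selected:
            continue
        res_in = fit(selected + [name])
        excluded[name] = (float(res_in.params[-1]), float(res_in.pvalues[-1]))
    return StepwiseModel(
        dependent=dependent_name,
        candidates=tuple(X.columns),
        selected=tuple(selected),
        beta_std=beta,
        p_values=pv,
        r_squared=r2,
        f_statistic=fstat,
        f_pvalue=fp,
        n=n,
        excluded=excluded,
    )


@dataclass(frozen=True)
class RoutingDecision:
    route: Literal["parametric", "nonparametric"]
    shapiro_p: dict[str, float]
    flagged: bool = False
    note: str = ""


def route_test(samples_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05) -> RoutingDecision:
    """Choose parametric vs non-parametric group comparison by normality.

    Parametric iff every group passes Shapiro-Wilk at ``alpha``.  Groups with
    n < 3 cannot be tested and route non-parametric with a flag.
    """
    pvals: dict[str, float] = {}
    for name, sample in samples_by_group.items():
        sample = np.asarray(sample, dtype=float)
        if sample.size < 3:
            return RoutingDecision(
                "nonparametric", pvals, flagged=True,
                note=f"group '{name}' has n={sample.size} < 3; normality untestable",
            )
        if np.ptp(sample) == 0:
            return RoutingDecision(
                "nonparametric", pvals, flagged=True,
                note=f"group '{name}' is constant; normality untestable",
            )
        pvals[name] = float(stats.shapiro(sample).pvalue)
    route = "parametric" if all(p > alpha for p in pvals.values()) else "nonparametric"
    return RoutingDecision(route, pvals)


def chi_square_2x2(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
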