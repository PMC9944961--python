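"""Baseline-category multinomial logistic profiling of the norm groups.

Characterizes latent groups by sociodemographic and psychosocial
covariates: a multinomial logit with the largest ("both against") group as
the reference outcome, fitted by Newton-Raphson with step-halving, Wald
standard errors from the observed information, and odds ratios with 95%
confidence intervals per non-reference group. Complete separation is
reported (flagged coefficients with unusable confidence intervals) rather
than penalized away; an optional ridge stabilizer is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = ["NewtonResult", "ProfileFit", "multinomial_newton", "fit_multinomial",
           "profile_table", "build_design"]

_SEP_COEF = 15.0  # |coefficient| beyond which we flag likely separation


@dataclass
class NewtonResult:
    coef: np.ndarray  # (K-1, P)
    se: np.ndarray  # (K-1, P)
    log_likelihood: float
    converged: bool
    n_iter: int
    ll_trace: list = field(default_factory=list)
    separation: np.ndarray | None = None  # boolean (K-1, P)


def _mnl_loglik(beta: np.ndarray, x: np.ndarray, onehot: np.ndarray) -> float:
    eta = np.concatenate(
        [np.zeros((x.shape[0], 1)), x @ beta.T], axis=1
    )
    return float(np.sum(eta * onehot) - logsumexp(eta, axis=1).sum())


def multinomial_newton(
    x: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> NewtonResult:
    """Maximum-likelihood multinomial logit (class 0 is the reference).

    Newton-Raphson with step-halving, so the log-likelihood never decreases
    across iterations. ``ridge`` adds an optional quadratic penalty used only
    to stabilize separated fits when explicitly requested.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    n, p = x.shape
    km1 = n_classes - 1
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    beta = np.zeros((km1, p))
    ll = _mnl_loglik(beta, x, onehot) - 0.5 * ridge * np.sum(beta**2)
    trace = [ll]
    converged = False
    it = 0
    hess = None
    for it in range(1, max_iter + 1):
        eta = np.concatenate([np.zeros((n, 1)), x @ beta.T], axis=1)
        prob = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))
        grad = np.concatenate(
            [x.T @ (onehot[:, k + 1] - prob[:, k + 1]) for k in range(km1)]
        ) - ridge * beta.ravel()
        hess = np.zeros((km1 * p, km1 * p))
        for a in range(km1):
            for b in range(a, km1):
                w = prob[:, a + 1] * ((a == b) - prob[:, b + 1])
                block = -(x * w[:, None]).T @ x
                hess[a * p:(a + 1) * p, b * p:(b + 1) * p] = block
                if a != b:
                    hess[b * p:(b + 1) * p, a * p:(a + 1) * p] = block
        hess -= ridge * np.eye(km1 * p)
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, -grad, rcond=None)[0]
        # step-halving keeps the trace non-decreasing
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step.reshape(km1, p)
            ll_new = _mnl_loglik(cand, x, onehot) - 0.5 * ridge * np.sum(cand**2)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        beta = cand
        trace.append(ll_new)
        if abs(ll_new - ll) < tol and np.max(np.abs(grad)) < 1e-6:
            ll, converged = ll_new, True
            break
        ll = ll_new
    # Wald standard errors from the observed information
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(km1, p)
    except np.linalg.LinAlgError:
        se = np.full((km1, p), np.nan)
    separation = (np.abs(beta) > _SEP_COEF) | ~np.isfinite(se) | (se > 1e3)
    return NewtonResult(beta, se, ll, converged, it, trace, separation)


@dataclass
class ProfileFit:
    """Per-class, per-covariate odds-ratio table plus fit metadata."""

    table: pd.DataFrame
    class_names: list
    reference_class: object
    converged: bool
    log_likelihood: float
    separation_flagged: bool


def build_design(
    covariates: pd.DataFrame,
    references: dict | None = None,
    standardize: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Expand a covariate frame into a design matrix with intercept.

    Categorical (object) columns are dummy-expanded against the stated
    reference level; numeric columns are optionally standardized to unit
    variance (scale coefficients then describe a one-s.d. increase).
    """
    references = references or {}
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names = ["intercept"]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(map(str, col.astype(str).unique()))
            ref = str(references.get(name, levels[0]))
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{name}={lev}")
        else:
            vals = col.to_numpy(float)
            if standardize:
                sd = vals.std()
                if sd > 0:
                    vals = (vals - vals.mean()) / sd
            cols.append(vals)
            names.append(name)
    return np.column_stack(cols), names


def fit_multinomial(
    groups,
    covariates: pd.DataFrame,
    reference_class=None,
    references: dict | None = None,
    standardize: bool = True,
    ridge: float = 0.0,
) -> ProfileFit:
    """Profile latent groups against covariates (Table-2-style output)."""
    groups = pd.Series(groups).reset_index(drop=True)
    levels = sorted(groups.unique())
    if reference_class is None:
        reference_class = groups.value_counts().idxmax()
    if reference_class not in levels:
        raise ValueError(f"reference class {reference_class!r} not among groups")
    others = [g for g in levels if g != reference_class]
    class_order = [reference_class] + others
    counts = groups.value_counts()
    if (counts.reindex(class_order).fillna(0) < 3).any():
        raise ValueError("need at least 3 observations per class")
    y = groups.map({g: i for i, g in enumerate(class_order)}).to_numpy()
    x, names = build_design(covariates.reset_index(drop=True), references, standardize)
    res = multinomial_newton(x, y, len(class_order), ridge=ridge)
    z = norm.ppf(0.975)
    rows = []
    for k, cls in enumerate(others):
        for j, name in enumerate(names):
            coef, se = res.coef[k, j], res.se[k, j]
            sep = bool(res.separation[k, j])
            pval = 2.0 * norm.sf(abs(coef) / se) if se > 0 and not sep else np.nan
            rows.append(
                {
                    "class": cls,
                    "covariate": name,
                    "coef": coef,
                    "se": se,
                    "odds_ratio": float(np.exp(coef)),
                    "ci_low": float(np.exp(coef - z * se)) if not sep else np.nan,
                    "ci_high": float(np.exp(coef + z * se)) if not sep else np.nan,
                    "p_value": pval,
                    "separation": sep,
                }
            )
    table = pd.DataFrame(rows)
    return ProfileFit(
        table=table,
        class_names=class_order,
        reference_class=reference_class,
        converged=res.converged,
        log_likelihood=res.log_likelihood,
        separation_flagged=bool(res.separation.any()),
    )


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def profile_table(fit: ProfileFit) -> pd.DataFrame:
    """Covariate rows x non-reference class columns of starred odds ratios."""
    t = fit.table.copy()
    t["display"] = [
        f"{orr:.3g}{_stars(p)}" for orr, p in zip(t["odds_ratio"], t["p_value"])
    ]
    wide = t.pivot(index="covariate", columns="class", values="display")
    order = [n for n in t["covariate"].unique()]
    return wide.loc[order]
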