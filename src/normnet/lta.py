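"""Latent transition analysis of the two norm scores across two waves.

A latent Markov model: each student occupies one of K latent classes at
baseline (initial probabilities pi) and transitions between waves according
to a K x K matrix tau. Conditional on the class, the two observed measures
(latent descriptive and injunctive norm scores) are independent Gaussians
whose means and variances are shared across waves (measurement invariance),
so a class means the same thing at both time points. Estimated by EM with
multiple seeded restarts; classes are interpreted afterwards by matching
their mean score profile to the three norm-group archetypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .influence import categorize_ego

__all__ = [
    "LTAModel",
    "fit_lta",
    "classification_certainty",
    "select_classes",
    "transition_table",
    "label_classes",
    "assign_students",
]

_VAR_FLOOR = 1e-6

#: archetypal (descriptive, injunctive) mean profiles of the three norm
#: groups on the [0, 1] score scale; classes are labeled by nearest archetype
ARCHETYPES = {
    "descriptive-favorable": np.array([1.0, 0.0]),
    "both-against": np.array([0.0, 0.0]),
    "injunctive-favorable": np.array([0.5, 1.0]),
}


@dataclass
class LTAModel:
    n_classes: int
    means: np.ndarray  # (K, M) shared across waves
    variances: np.ndarray  # (K, M)
    pi: np.ndarray  # (K,)
    tau: np.ndarray  # (K, K), rows on the simplex
    log_likelihood: float
    bic: float
    n_obs: int
    relative_entropy: float = float("nan")
    variance_floored: bool = False
    class_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must lie on the simplex")
        if np.abs(self.tau.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("tau rows must lie on the simplex")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")


def _emission_loglik(y: np.ndarray, means: np.ndarray, variances: np.ndarray):
    """(N, K) log density of each wave's observation under each class."""
    return norm.logpdf(
        y[:, None, :], loc=means[None], scale=np.sqrt(variances)[None]
    ).sum(axis=2)


def _posteriors(model: LTAModel, y1: np.ndarray, y2: np.ndarray):
    """Joint and marginal class posteriors plus the log-likelihood."""
    lf1 = _emission_loglik(y1, model.means, model.variances)
    lf2 = _emission_loglik(y2, model.means, model.variances)
    with np.errstate(divide="ignore"):
        log_joint = (
            np.log(np.maximum(model.pi, 1e-300))[None, :, None]
            + np.log(np.maximum(model.tau, 1e-300))[None, :, :]
            + lf1[:, :, None]
            + lf2[:, None, :]
        )
    ll_i = logsumexp(log_joint, axis=(1, 2))
    joint = np.exp(log_joint - ll_i[:, None, None])
    return joint, joint.sum(axis=2), joint.sum(axis=1), float(ll_i.sum())


def _n_params(k: int, m: int) -> int:
    return (k - 1) + k * (k - 1) + 2 * k * m


def _em_once(
    y1: np.ndarray,
    y2: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
):
    n, m = y1.shape
    pick = rng.choice(n, size=k, replace=False)
    means = y1[pick].copy()
    variances = np.tile(np.vstack([y1, y2]).var(axis=0) + 1e-4, (k, 1))
    pi = np.full(k, 1.0 / k)
    tau = np.full((k, k), 0.2 / max(k - 1, 1)) if k > 1 else np.ones((1, 1))
    if k > 1:
        np.fill_diagonal(tau, 0.8)
    floored = False
    ll_old = -np.inf
    trace = []
    for _ in range(max_iter):
        model = LTAModel(
            k, means, variances, pi, tau, ll_old, np.nan, n, variance_floored=floored
        )
        joint, g1, g2, ll = _posteriors(model, y1, y2)
        trace.append(ll)
        if ll - ll_old < tol and np.isfinite(ll_old):
            break
        ll_old = ll
        pi = g1.mean(axis=0)
        pi = pi / pi.sum()
        denom = g1.sum(axis=0)
        tau = joint.sum(axis=0) / np.maximum(denom, 1e-12)[:, None]
        row_sums = tau.sum(axis=1, keepdims=True)
        # a (near-)empty baseline class gets uniform transitions; the cutoff
        # also guards against subnormal sums whose renormalization is inexact
        empty = row_sums[:, 0] < 1e-12
        tau[empty] = 1.0 / k
        tau[~empty] = tau[~empty] / row_sums[~empty]
        wsum = g1.sum(axis=0) + g2.sum(axis=0)
        means = (g1.T @ y1 + g2.T @ y2) / np.maximum(wsum, 1e-12)[:, None]
        sq = g1.T @ y1**2 + g2.T @ y2**2
        variances = sq / np.maximum(wsum, 1e-12)[:, None] - means**2
        if (variances < _VAR_FLOOR).any():
            floored = True
        variances = np.maximum(variances, _VAR_FLOOR)
    return means, variances, pi, tau, ll_old, floored, trace


def fit_lta(
    y1: np.ndarray,
    y2: np.ndarray,
    n_classes: int,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> LTAModel:
    """EM fit of the two-wave latent Markov model, keeping the best restart.

    ``y1`` and ``y2`` are the (N, M) score matrices at baseline and
    follow-up for complete cases only.
    """
    y1 = np.atleast_2d(np.asarray(y1, float))
    y2 = np.atleast_2d(np.asarray(y2, float))
    if y1.shape != y2.shape:
        raise ValueError("wave score matrices must have matching shape")
    if np.isnan(y1).any() or np.isnan(y2).any():
        raise ValueError("complete cases only")
    if n_classes < 1:
        raise ValueError("need at least one class")
    n, m = y1.shape
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_restarts, 1)):
        out = _em_once(y1, y2, n_classes, rng, max_iter, tol)
        if best is None or out[4] > best[4]:
            best = out
    means, variances, pi, tau, ll, floored, _ = best
    if floored:
        warnings.warn("degenerate class variance floored during EM", stacklevel=2)
    bic = -2.0 * ll + _n_params(n_classes, m) * np.log(n)
    model = LTAModel(
        n_classes, means, variances, pi, tau, ll, float(bic), n,
        variance_floored=floored,
    )
    model.relative_entropy = classification_certainty(model, y1, y2)
    model.class_labels = label_classes(model)
    return model


def em_trace(y1, y2, n_classes: int, seed: int = 0, max_iter: int = 200):
    """Log-likelihood trace of a single EM run (diagnostic helper)."""
    y1 = np.atleast_2d(np.asarray(y1, float))
    y2 = np.atleast_2d(np.asarray(y2, float))
    rng = np.random.default_rng(seed)
    return _em_once(y1, y2, n_classes, rng, max_iter, 1e-12)[6]


def classification_certainty(model: LTAModel, y1, y2) -> float:
    """Relative-entropy certainty statistic, averaged over the two waves.

    1 - sum_i sum_k p_ik log p_ik / (N log K): 1 for fully determinate
    posteriors, 0 for uniform ones. Defined as 1 when K = 1.
    """
    if model.n_classes == 1:
        return 1.0
    _, g1, g2, _ = _posteriors(model, np.atleast_2d(y1), np.atleast_2d(y2))
    n = g1.shape[0]
    vals = []
    for g in (g1, g2):
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(g > 0, g * np.log(g), 0.0))
        vals.append(1.0 - ent / (n * np.log(model.n_classes)))
    return float(np.mean(vals))


def select_classes(
    y1, y2, k_range, seed: int = 0, n_restarts: int = 10
) -> tuple[int, dict[int, float]]:
    """Fit each candidate class count and pick the BIC minimizer."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty K range")
    scores = {}
    for j, k in enumerate(k_range):
        fit = fit_lta(y1, y2, k, n_restarts=n_restarts, seed=seed + 97 * j)
        scores[k] = fit.bic
    best = min(scores, key=scores.get)
    return best, scores


def label_classes(model: LTAModel) -> list[str]:
    """Name classes by their nearest norm-group archetype.

    Mean profiles (descriptive, injunctive) are matched to the archetypes:
    high descriptive / low injunctive -> descriptive-favorable; low/low ->
    both-against; high injunctive -> injunctive-favorable. If two classes
    share a nearest archetype, labels follow distance order with a warning.
    """
    names = list(ARCHETYPES)
    protos = np.stack([ARCHETYPES[a] for a in names])
    dist = np.linalg.norm(model.means[:, None, :2] - protos[None], axis=2)
    nearest = dist.argmin(axis=1)
    labels = [names[a] for a in nearest]
    if len(set(labels)) < len(labels):
        warnings.warn(
            "multiple classes share the nearest norm-group archetype", stacklevel=2
        )
    return labels


def side_of_label(label: str) -> str:
    return "against" if label == "both-against" else "favorable"


def assign_students(
    model: LTAModel, scores: pd.DataFrame
) -> pd.DataFrame:
    """Modal class and favorable/against side per student per wave.

    ``scores`` is the complete-case score frame in wide form with columns
    ``school, student, descriptive_t0, injunctive_t0, descriptive_t1,
    injunctive_t1`` (see :func:`wide_scores`).
    """
    y1 = scores[["descriptive_t0", "injunctive_t0"]].to_numpy(float)
    y2 = scores[["descriptive_t1", "injunctive_t1"]].to_numpy(float)
    joint, g1, g2, _ = _posteriors(model, y1, y2)
    labels = model.class_labels or label_classes(model)
    out = scores[["school", "student"]].copy()
    out["class_t0"] = g1.argmax(axis=1) + 1
    out["class_t1"] = g2.argmax(axis=1) + 1
    out["side_t0"] = [side_of_label(labels[c - 1]) for c in out["class_t0"]]
    out["side_t1"] = [side_of_label(labels[c - 1]) for c in out["class_t1"]]
    out["transition_category"] = [
        categorize_ego(s0, s1) for s0, s1 in zip(out["side_t0"], out["side_t1"])
    ]
    for k in range(model.n_classes):
        out[f"post_t0_{k + 1}"] = g1[:, k]
        out[f"post_t1_{k + 1}"] = g2[:, k]
    return out


def wide_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long score frame to one complete-case row per student."""
    complete = scores[scores["complete"]]
    wide = complete.pivot_table(
        index=["school", "student"],
        columns="wave",
        values=["descriptive", "injunctive"],
        aggfunc="first",
    )
    wide.columns = [
        f"{measure}_t{0 if wave == 'baseline' else 1}" for measure, wave in wide.columns
    ]
    return wide.reset_index().dropna()


def transition_table(
    assignments: pd.DataFrame, attributes: pd.DataFrame | None = None
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Class-to-class transition counts and a prevalence-by-arm table.

    Returns the K x K count matrix (rows = baseline class, columns =
    follow-up class) and, when per-student intervention labels are
    available, per intervention x wave class prevalences in percent
    (columns summing to 100).
    """
    k = int(max(assignments["class_t0"].max(), assignments["class_t1"].max()))
    counts = np.zeros((k, k), dtype=int)
    for c0, c1 in zip(assignments["class_t0"], assignments["class_t1"]):
        counts[c0 - 1, c1 - 1] += 1
    prevalence = None
    if attributes is not None:
        arm = (
            attributes[["school", "student", "intervention"]]
            .drop_duplicates(subset=["school", "student"])
        )
        merged = assignments.merge(arm, on=["school", "student"], how="left")
        rows = []
        for (interv,), sub in merged.groupby(["intervention"]):
            for wave, col in (("baseline", "class_t0"), ("followup", "class_t1")):
                shares = (
                    sub[col].value_counts(normalize=True).reindex(
                        range(1, k + 1), fill_value=0.0
                    )
                    * 100.0
                )
                for cls, pct in shares.items():
                    rows.append(
                        {
                            "intervention": interv,
                            "wave": wave,
                            "class": cls,
                            "percent": pct,
                        }
                    )
        prevalence = pd.DataFrame(rows)
    return counts, prevalence
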