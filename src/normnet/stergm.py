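"""Separable temporal ERGM for two-wave directed friendship networks.

Between two observations y^{t-1} -> y^t, tie *formation* and tie
*dissolution* are modelled as independent exponential-family processes
conditional on the earlier network. The formation network y+ = y^{t-1} U
y^t collects every tie present at either wave; the dissolution network
y- = y^{t-1} n y^t collects the surviving ties. Each phase has its own
statistics and coefficients:

    Pr(Y+ = y+ | y^{t-1}) prop. to exp(theta+ . g+(y+, y^{t-1}))   over supersets
    Pr(Y- = y- | y^{t-1}) prop. to exp(theta- . g-(y-, y^{t-1}))   over subsets

Statistics available: ``edges`` (baseline rate), ``mutual`` (reciprocity),
``transitive`` (transitive ties: ties i->j closed by some two-path
i->k->j), and ``same_side`` (norm-group homophily: ego and alter share the
favorable/against side — baseline side for formation, follow-up side for
dissolution). Dissolution coefficients parameterize tie persistence:
positive values mean ties last longer.

Estimation is by maximum pseudolikelihood (MPLE): a logistic regression of
each eligible dyad's state on its change statistics, exact for
dyad-independent specifications and approximate (with approximate Wald
p-values) when the transitive term makes dyads dependent. A
Metropolis-within-Gibbs simulator over each phase's dyad space supports
simulation-based checks of the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .data import TwoWaveNetwork
from .profiles import multinomial_newton

__all__ = [
    "StergmSpec",
    "FormationDissolutionPair",
    "StergmFit",
    "build_pair",
    "change_statistic",
    "change_stats_matrix",
    "network_statistics",
    "mple_fit",
    "simulate_stergm",
    "fit_all_schools",
]

KNOWN_STATS = ("edges", "mutual", "transitive", "same_side")


@dataclass(frozen=True)
class StergmSpec:
    """Statistics used in each phase; ``edges`` must always be present."""

    formation: tuple = ("edges", "mutual", "transitive", "same_side")
    dissolution: tuple = ("edges", "mutual", "transitive", "same_side")

    def __post_init__(self) -> None:
        for phase, stats in (("formation", self.formation), ("dissolution", self.dissolution)):
            if "edges" not in stats:
                raise ValueError(f"{phase} statistics must include 'edges'")
            if len(set(stats)) != len(stats):
                raise ValueError(f"duplicate statistic in {phase}")
            unknown = set(stats) - set(KNOWN_STATS)
            if unknown:
                raise ValueError(f"unknown statistics {sorted(unknown)}")


@dataclass
class FormationDissolutionPair:
    """y+ (union) and y- (intersection) adjacency with the baseline y^{t-1}."""

    y_prev: np.ndarray
    y_plus: np.ndarray
    y_minus: np.ndarray
    roster: tuple

    def y_next(self) -> np.ndarray:
        """Reconstruct the follow-up network: y- plus the newly formed ties."""
        return (self.y_minus | (self.y_plus & ~self.y_prev.astype(bool))).astype(np.int8)


def build_pair(two_wave: TwoWaveNetwork) -> FormationDissolutionPair:
    a0 = two_wave.adjacency(two_wave.wave_labels[0]).astype(bool)
    a1 = two_wave.adjacency(two_wave.wave_labels[1]).astype(bool)
    return FormationDissolutionPair(
        y_prev=a0.astype(np.int8),
        y_plus=(a0 | a1).astype(np.int8),
        y_minus=(a0 & a1).astype(np.int8),
        roster=two_wave.roster,
    )


# --------------------------------------------------------------------------
# statistics


def network_statistics(adj: np.ndarray, stats, side: np.ndarray | None = None):
    """Full statistic values g(y) on a directed adjacency matrix."""
    a = np.asarray(adj, dtype=np.int8)
    s2 = a.astype(np.int64) @ a.astype(np.int64)
    out = {}
    for name in stats:
        if name == "edges":
            out[name] = int(a.sum())
        elif name == "mutual":
            out[name] = int((a & a.T).sum()) // 2
        elif name == "transitive":
            out[name] = int((a * (s2 > 0)).sum())
        elif name == "same_side":
            if side is None:
                raise ValueError("same_side requires a side attribute")
            same = side[:, None] == side[None, :]
            out[name] = int((a * same).sum())
        else:
            raise ValueError(f"unknown statistic {name!r}")
    return out


def change_stats_matrix(
    adj: np.ndarray, stats, side: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Per-dyad change statistics (toggle each dyad on, rest at observed).

    Entry (i, j) is g(y with the tie i->j present) - g(y with it absent),
    all other dyads held at their observed state in ``adj``.
    """
    a = np.asarray(adj, dtype=np.int8)
    n = a.shape[0]
    out: dict[str, np.ndarray] = {}
    s2 = None
    for name in stats:
        if name == "edges":
            out[name] = np.ones((n, n))
        elif name == "mutual":
            out[name] = a.T.astype(float)
        elif name == "same_side":
            if side is None:
                raise ValueError("same_side requires a side attribute")
            out[name] = (side[:, None] == side[None, :]).astype(float)
        elif name == "transitive":
            af = a.astype(np.int64)
            s2 = af @ af if s2 is None else s2
            term1 = (s2 > 0).astype(float)
            z0 = (s2 == 0).astype(np.int64)
            z1 = (s2 == 1).astype(np.int64)
            # new transitive status for edges (i,b) via the path i->j->b
            t2_0 = (af * z0) @ af.T  # used where the focal tie is absent
            t2_1 = (af * z1) @ af.T  # the focal tie itself supplies one path
            term2 = np.where(a == 1, t2_1, t2_0).astype(float)
            # new transitive status for edges (a,j) via the path a->i->j
            t3_0 = af.T @ (af * z0)
            t3_1 = af.T @ (af * z1)
            term3 = np.where(a == 1, t3_1, t3_0).astype(float)
            out[name] = term1 + term2 + term3
        else:
            raise ValueError(f"unknown statistic {name!r}")
        np.fill_diagonal(out[name], 0.0)
    return out


def change_statistic(
    stat: str, dyad: tuple[int, int], adj: np.ndarray, side: np.ndarray | None = None
) -> float:
    """Change in one statistic from toggling a single ordered dyad on."""
    i, j = dyad
    if i == j:
        raise ValueError("self-pairs are not valid dyads")
    return float(change_stats_matrix(adj, [stat], side)[stat][i, j])


# --------------------------------------------------------------------------
# estimation


@dataclass
class StergmFit:
    formation: pd.DataFrame  # term, coef, se, p_value, flagged
    dissolution: pd.DataFrame
    method: str = "MPLE"
    school: str = "school"
    diagnostics: dict = field(default_factory=dict)


def _phase_mple(
    context_adj: np.ndarray,
    response: np.ndarray,
    eligible: np.ndarray,
    stats,
    side: np.ndarray | None,
) -> pd.DataFrame:
    deltas = change_stats_matrix(context_adj, stats, side)
    x = np.column_stack([deltas[name][eligible] for name in stats])
    y = response[eligible].astype(int)
    rows = []
    if len(np.unique(y)) < 2:
        for name in stats:
            rows.append(
                {"term": name, "coef": np.nan, "se": np.nan, "p_value": np.nan,
                 "flagged": True}
            )
        return pd.DataFrame(rows)
    res = multinomial_newton(x, y, 2)
    coef, se = res.coef[0], res.se[0]
    flagged = res.separation[0] | (not res.converged)
    for k, name in enumerate(stats):
        ok = np.isfinite(se[k]) and se[k] > 0 and not flagged[k]
        rows.append(
            {
                "term": name,
                "coef": coef[k] if not flagged[k] else np.nan,
                "se": se[k] if ok else np.nan,
                "p_value": 2.0 * norm.sf(abs(coef[k]) / se[k]) if ok else np.nan,
                "flagged": bool(flagged[k]),
            }
        )
    return pd.DataFrame(rows)


def mple_fit(
    pair: FormationDissolutionPair,
    spec: StergmSpec,
    side_t0: np.ndarray | None = None,
    side_t1: np.ndarray | None = None,
    school: str = "school",
) -> StergmFit:
    """Pseudolikelihood fit of both phases.

    Formation: logistic regression over dyads empty in y^{t-1}, response =
    present in y+, change statistics evaluated in the formation network
    (homophily on the baseline side). Dissolution: over dyads of y^{t-1},
    response = retained in y-, statistics in the dissolution network
    (homophily on the follow-up side).
    """
    n = pair.y_prev.shape[0]
    off_diag = ~np.eye(n, dtype=bool)
    form_elig = (pair.y_prev == 0) & off_diag
    diss_elig = pair.y_prev == 1
    formation = _phase_mple(
        pair.y_plus, pair.y_plus.astype(bool), form_elig, spec.formation, side_t0
    )
    dissolution = _phase_mple(
        pair.y_minus, pair.y_minus.astype(bool), diss_elig, spec.dissolution, side_t1
    )
    return StergmFit(formation=formation, dissolution=dissolution, school=school)


# --------------------------------------------------------------------------
# simulation


def _transitive_delta_scalar(adj: np.ndarray, i: int, j: int) -> float:
    """O(n) transitive-ties change for one dyad (used inside the sampler)."""
    af = adj.astype(np.int64)
    aij = int(af[i, j])
    tp_i = af[i] @ af  # two-path counts i -> b
    term1 = 1 if tp_i[j] > 0 else 0
    mask2 = (af[i] == 1) & (af[j] == 1)
    term2 = int(np.sum(mask2 & (tp_i - aij * af[j] == 0)))
    tp_j = af @ af[:, j]  # two-path counts a -> j
    mask3 = (af[:, j] == 1) & (af[:, i] == 1)
    term3 = int(np.sum(mask3 & (tp_j - aij == 0)))
    return float(term1 + term2 + term3)


def _gibbs_phase(
    rng: np.random.Generator,
    fixed: np.ndarray,  # ties clamped on (formation) -- int8
    free: np.ndarray,  # boolean mask of toggleable dyads
    init: np.ndarray,
    stats,
    theta: np.ndarray,
    side: np.ndarray | None,
    n_sweeps: int,
) -> np.ndarray:
    adj = init.copy()
    dyads = np.argwhere(free)
    for _ in range(n_sweeps):
        order = rng.permutation(len(dyads))
        for idx in order:
            i, j = dyads[idx]
            vals = []
            for s in stats:
                if s == "edges":
                    vals.append(1.0)
                elif s == "mutual":
                    vals.append(float(adj[j, i]))
                elif s == "same_side":
                    vals.append(float(side[i] == side[j]))
                elif s == "transitive":
                    vals.append(_transitive_delta_scalar(adj, i, j))
            delta = np.array(vals)
            p_on = expit(float(theta @ delta))
            adj[i, j] = 1 if rng.random() < p_on else 0
    return (adj | fixed).astype(np.int8)


def simulate_stergm(
    y_prev: np.ndarray,
    spec: StergmSpec,
    theta_plus: np.ndarray,
    theta_minus: np.ndarray,
    side_t0: np.ndarray | None = None,
    side_t1: np.ndarray | None = None,
    n_sweeps: int = 30,
    seed: int = 0,
    return_pair: bool = False,
):
    """Draw a follow-up network from the separable model given y^{t-1}.

    Gibbs sampling toggles each eligible dyad from its full conditional,
    separately over the formation space (supersets of y^{t-1}) and the
    dissolution space (subsets), then composes
    y^t = y- U (y+ minus y^{t-1}).
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be at least 1")
    theta_plus = np.asarray(theta_plus, float)
    theta_minus = np.asarray(theta_minus, float)
    if not (np.isfinite(theta_plus).all() and np.isfinite(theta_minus).all()):
        raise ValueError("coefficients must be finite")
    a0 = np.asarray(y_prev, dtype=np.int8)
    n = a0.shape[0]
    rng = np.random.default_rng(seed)
    off_diag = ~np.eye(n, dtype=bool)

    form_free = (a0 == 0) & off_diag
    y_plus = _gibbs_phase(
        rng, a0, form_free, a0.copy(), spec.formation, theta_plus, side_t0, n_sweeps
    )
    diss_free = a0 == 1
    y_minus = _gibbs_phase(
        rng,
        np.zeros_like(a0),
        diss_free,
        a0.copy(),
        spec.dissolution,
        theta_minus,
        side_t1,
        n_sweeps,
    )
    pair = FormationDissolutionPair(
        y_prev=a0, y_plus=y_plus, y_minus=y_minus, roster=tuple(range(n))
    )
    return pair if return_pair else pair.y_next()


# --------------------------------------------------------------------------
# study-level report


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def fit_all_schools(
    networks: list[TwoWaveNetwork],
    assignments: pd.DataFrame,
    spec: StergmSpec | None = None,
) -> pd.DataFrame:
    """One formation + dissolution MPLE fit per school (Table-4 layout).

    Networks are restricted to students with a norm-side assignment
    (complete cases); non-converged or separated terms are reported as N/A.
    """
    spec = spec or StergmSpec()
    rows = []
    for net in networks:
        sub = assignments[assignments["school"] == net.school]
        side0 = dict(zip(sub["student"], sub["side_t0"]))
        side1 = dict(zip(sub["student"], sub["side_t1"]))
        keep = [s for s in net.roster if s in side0]
        if len(keep) < 3:
            continue
        keep_set = set(keep)
        restricted = TwoWaveNetwork(
            tuple(keep),
            {t for t in net.ties_t0 if t[0] in keep_set and t[1] in keep_set},
            {t for t in net.ties_t1 if t[0] in keep_set and t[1] in keep_set},
            school=net.school,
        )
        pair = build_pair(restricted)
        s0 = np.array([side0[s] for s in keep])
        s1 = np.array([side1[s] for s in keep])
        fit = mple_fit(pair, spec, side_t0=s0, side_t1=s1, school=net.school)
        for phase, frame in (("formation", fit.formation), ("dissolution", fit.dissolution)):
            for r in frame.itertuples():
                rows.append(
                    {
                        "school": net.school,
                        "phase": phase,
                        "term": r.term,
                        "coef": r.coef,
                        "se": r.se,
                        "p_value": r.p_value,
                        "stars": _stars(r.p_value) if not r.flagged else "N/A",
                        "flagged": r.flagged,
                    }
                )
    return pd.DataFrame(rows)
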