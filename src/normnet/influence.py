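"""Descriptive analysis of peer influence on norm-group transitions.

Each student (ego) is placed in one of four transition categories by their
favorable/against norm side at the two waves: maintain-against,
maintain-favorable, change-to-against, change-to-favorable. Friendship ties
are partitioned into persisting, new (follow-up only) and dropped (baseline
only) sets, and for each ego category the composition of friends'
transition categories is averaged per ego (each ego contributes one
normalized distribution). The network-threshold analysis compares, across
ego categories, the baseline share of out-neighbors on the favorable side.
"Friends" are out-neighbors: the nominations an ego made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .data import TwoWaveNetwork

__all__ = [
    "TiePartition",
    "EGO_CATEGORIES",
    "partition_ties",
    "categorize_ego",
    "friend_change_profile",
    "baseline_threshold_table",
    "transition_intervention_chisq",
]

EGO_CATEGORIES = (
    "maintain-against",
    "maintain-favorable",
    "change-to-against",
    "change-to-favorable",
)

TIE_CLASSES = ("persisting", "new", "dropped")


@dataclass(frozen=True)
class TiePartition:
    persisting: frozenset
    new: frozenset
    dropped: frozenset


def partition_ties(two_wave: TwoWaveNetwork) -> TiePartition:
    t0, t1 = two_wave.ties_t0, two_wave.ties_t1
    return TiePartition(
        persisting=frozenset(t0 & t1),
        new=frozenset(t1 - t0),
        dropped=frozenset(t0 - t1),
    )


def categorize_ego(side_t0: str, side_t1: str) -> str:
    for side in (side_t0, side_t1):
        if side not in ("favorable", "against"):
            raise ValueError(f"unknown norm side {side!r}")
    if side_t0 == side_t1:
        return f"maintain-{side_t0}"
    return f"change-to-{side_t1}"


def _tie_sets(partition: TiePartition) -> dict[str, frozenset]:
    return {
        "persisting": partition.persisting,
        "new": partition.new,
        "dropped": partition.dropped,
    }


def friend_change_profile(
    assignments: pd.DataFrame,
    networks: list[TwoWaveNetwork],
    attributes: pd.DataFrame | None = None,
    tie_pooled: bool = False,
) -> pd.DataFrame:
    """Average composition of friends' transition categories.

    For every ego category x tie class (x setting and intervention when
    ``attributes`` is given): the distribution of friends' transition
    categories, ego-averaged by default (each ego contributes one
    normalized distribution) or tie-pooled when ``tie_pooled``.
    Egos or friends without complete assignments are skipped.
    """
    cat = {
        (r.school, r.student): r.transition_category
        for r in assignments.itertuples()
    }
    strata = {}
    if attributes is not None:
        meta = attributes[
            ["school", "student", "setting", "intervention"]
        ].drop_duplicates(subset=["school", "student"])
        strata = {
            (r.school, r.student): (r.setting, r.intervention)
            for r in meta.itertuples()
        }
    acc: dict[tuple, list] = {}
    for net in networks:
        parts = _tie_sets(partition_ties(net))
        for tie_class, ties in parts.items():
            by_ego: dict[str, np.ndarray] = {}
            for ego, alter in sorted(ties):  # sorted for reproducible output order
                ego_cat = cat.get((net.school, ego))
                alter_cat = cat.get((net.school, alter))
                if ego_cat is None or alter_cat is None:
                    continue
                vec = by_ego.setdefault(ego, np.zeros(len(EGO_CATEGORIES)))
                vec[EGO_CATEGORIES.index(alter_cat)] += 1
            for ego, vec in by_ego.items():
                ego_cat = cat[(net.school, ego)]
                setting, interv = strata.get((net.school, ego), ("all", "all"))
                key = (ego_cat, tie_class, setting, interv)
                acc.setdefault(key, []).append(
                    vec if tie_pooled else vec / vec.sum()
                )
    rows = []
    for (ego_cat, tie_class, setting, interv), dists in acc.items():
        stacked = np.stack(dists)
        if tie_pooled:
            total = stacked.sum(axis=0)
            mean = total / total.sum()
        else:
            mean = stacked.mean(axis=0)
        for j, friend_cat in enumerate(EGO_CATEGORIES):
            rows.append(
                {
                    "ego_category": ego_cat,
                    "tie_class": tie_class,
                    "setting": setting,
                    "intervention": interv,
                    "friend_category": friend_cat,
                    "proportion": mean[j],
                    "n_egos": len(dists),
                }
            )
    return pd.DataFrame(rows)


def baseline_threshold_table(
    assignments: pd.DataFrame, networks: list[TwoWaveNetwork]
) -> pd.DataFrame:
    """Mean baseline favorable-friend share per ego transition category.

    The share is favorable baseline out-neighbors over baseline out-degree;
    egos with no baseline nominations are excluded (their count reported).
    """
    cat = {
        (r.school, r.student): r.transition_category
        for r in assignments.itertuples()
    }
    side0 = {(r.school, r.student): r.side_t0 for r in assignments.itertuples()}
    shares: dict[str, list[float]] = {c: [] for c in EGO_CATEGORIES}
    n_isolated = 0
    for net in networks:
        out_nbrs: dict[str, list] = {}
        for ego, alter in sorted(net.ties_t0):
            out_nbrs.setdefault(ego, []).append(alter)
        for ego_key, ego_cat in cat.items():
            school, ego = ego_key
            if school != net.school:
                continue
            nbrs = out_nbrs.get(ego)
            if not nbrs:
                n_isolated += 1
                continue
            known = [side0.get((school, a)) for a in nbrs]
            known = [s for s in known if s is not None]
            if not known:
                continue
            shares[ego_cat].append(
                sum(s == "favorable" for s in known) / len(known)
            )
    rows = [
        {
            "ego_category": c,
            "mean_favorable_share": float(np.mean(v)) if v else np.nan,
            "n_egos": len(v),
        }
        for c, v in shares.items()
    ]
    table = pd.DataFrame(rows)
    table.attrs["n_isolated_excluded"] = n_isolated
    return table


def transition_intervention_chisq(
    assignments: pd.DataFrame, attributes: pd.DataFrame
) -> tuple[float, int, float, np.ndarray]:
    """Pearson chi-square of transition-to-against by intervention arm.

    Among at-risk egos (on the favorable side at baseline), cross-tabulates
    whether they changed to the against side by follow-up against the
    intervention arm of their school, and tests independence with an
    uncorrected Pearson chi-square on the 2 x 2 table (df = 1). A warning
    is attached to the result when any expected cell is below 1.
    """
    arm = attributes[["school", "student", "intervention"]].drop_duplicates(
        subset=["school", "student"]
    )
    merged = assignments.merge(arm, on=["school", "student"], how="inner")
    at_risk = merged[merged["side_t0"] == "favorable"]
    if at_risk.empty:
        raise ValueError("no at-risk (baseline-favorable) egos")
    changed = at_risk["side_t1"] == "against"
    table = pd.crosstab(changed, at_risk["intervention"]).reindex(
        index=[True, False], fill_value=0
    )
    if table.shape != (2, 2):
        raise ValueError("need exactly two intervention arms")
    obs = table.to_numpy(float)
    stat, p, dof, expected = chi2_contingency(obs, correction=False)
    result_warning = bool((expected < 1).any())
    out = (float(stat), int(dof), float(p), obs)
    if result_warning:
        import warnings

        warnings.warn("expected cell count below 1 in chi-square table", stacklevel=2)
    return out
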