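"""Synthetic two-wave school friendship cohorts with planted norm dynamics.

The generator emulates the observable structure of a two-country,
twelve-school smoking-prevention study: directed friendship nominations
(up to ten per student) observed at baseline and follow-up, plus per-student
demographics, psychosocial scales and raw smoking-norm items. Three latent
norm groups with highly unbalanced prevalence are planted, together with
tunable attribute homophily in tie formation and tunable peer influence on
group transitions, so every downstream analysis stage can be exercised and
calibrated against known effect sizes.

Tie model (baseline): for each unordered pair of students, the two directed
nominations are drawn jointly from a dyad-independent exponential model

    P(x_ij, x_ji) proportional to exp(b (x_ij + x_ji)
                                      + h * same_group * (x_ij + x_ji)
                                      + m * x_ij * x_ji)

where ``h`` is the same-group log-odds bonus (homophily), ``m`` a mutuality
bonus, and the base rate ``b`` is calibrated numerically so the expected
mean out-degree matches the target. Out-degrees are then truncated to the
nomination cap by random removal. Follow-up ties keep each baseline tie with
probability ``tie_persistence`` and add new ties drawn from the same dyad
model at a rate calibrated to keep the expected tie count stable.

Group transitions between waves act on the favorable/against dichotomy: the
log-odds of being on the favorable side at follow-up gain
``influence_strength`` per baseline out-neighbor on the favorable side, and
peer-led schools receive an extra shift toward the against side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .data import (
    FAVORABLE_GROUPS,
    GROUPS,
    ITEM_FAMILIES,
    WAVES,
    TwoWaveNetwork,
    item_columns,
    side_of_group,
    validate_student_table,
)

__all__ = [
    "CohortConfig",
    "generate_school",
    "generate_study",
    "inject_missingness",
]

#: default group mean (descriptive, injunctive) scores on the [0, 1] scale:
#: group 1 high descriptive / low injunctive, group 2 both against,
#: group 3 high injunctive.
DEFAULT_GROUP_MEANS = {
    1: (0.55, 0.15),
    2: (0.12, 0.10),
    3: (0.30, 0.62),
}

#: baseline-side persistence of the favorable/against dichotomy, chosen to
#: mirror a regime where roughly 40% of favorable students revert to against
#: between waves while about 5% of against students become favorable.
P_STAY_FAVORABLE = 0.60
P_BECOME_FAVORABLE = 0.05


def _default_assignment(labels: tuple[str, str]):
    def assign(school_index: int, n_schools: int) -> str:
        return labels[0] if school_index < n_schools / 2 else labels[1]

    return assign


@dataclass
class CohortConfig:
    """Study-level knobs of the synthetic cohort.

    The defaults describe the emulated study conditions: 12 schools of
    77-177 students, up to 10 nominations, mean in-degree about 6.5,
    between-wave tie persistence yielding Jaccard indices in the gradual
    change band, and three norm groups at roughly 11% / 86% / 2% prevalence.
    """

    n_schools: int = 12
    school_size_range: tuple[int, int] = (77, 177)
    max_nominations: int = 10
    target_in_degree: float = 6.5
    tie_persistence: float = 0.62
    group_prevalence: tuple[float, float, float] = (0.114, 0.862, 0.024)
    norm_group_means: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_MEANS))
    homophily_strength: float = 0.15
    mutuality_strength: float = 2.0
    formation_reciprocity: float = 1.0
    dissolution_reciprocity: float = 0.7
    influence_strength: float = 0.5
    intervention_effect: float = 0.6
    item_noise_sd: float = 0.1
    student_noise_sd: float = 0.05
    intervention_assignment: dict | None = None  # school name -> label
    setting_assignment: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.school_size_range
        if lo < 20 or hi > 500 or lo > hi:
            raise ValueError(
                f"school_size_range {self.school_size_range} outside [20, 500]"
            )
        prev = np.asarray(self.group_prevalence, dtype=float)
        if prev.shape != (3,) or abs(prev.sum() - 1.0) > 1e-9 or (prev <= 0).any():
            raise ValueError("group_prevalence must be 3 positive values summing to 1")
        if not 0.0 <= self.tie_persistence <= 1.0:
            raise ValueError("tie_persistence must lie in [0, 1]")
        if self.max_nominations < 1:
            raise ValueError("max_nominations must be positive")

    def school_name(self, school_index: int) -> str:
        return f"school{school_index + 1:02d}"

    def setting_of(self, school_index: int) -> str:
        name = self.school_name(school_index)
        if self.setting_assignment is not None:
            return self.setting_assignment[name]
        return "NI" if school_index < self.n_schools / 2 else "COL"

    def intervention_of(self, school_index: int) -> str:
        name = self.school_name(school_index)
        if self.intervention_assignment is not None:
            return self.intervention_assignment[name]
        # global alternation balances arms overall and within each setting
        # (3 per setting x intervention in the 12-school layout)
        return "peer-led" if school_index % 2 == 0 else "teacher-led"


# --------------------------------------------------------------------------
# dyad model internals


def _pair_expected_ties(b: np.ndarray | float, h_same: np.ndarray, m: float):
    """Expected number of directed ties on an unordered pair."""
    a = b + h_same
    e1 = np.exp(a)
    e2 = np.exp(2.0 * a + m)
    z = 1.0 + 2.0 * e1 + e2
    return (2.0 * e1 + 2.0 * e2) / z


def _calibrate_base_rate(
    groups: np.ndarray, target_in_degree: float, h: float, m: float
) -> float:
    """Solve for the base log-odds so expected ties/node hits the target."""
    n = len(groups)
    iu, ju = np.triu_indices(n, k=1)
    same = (groups[iu] == groups[ju]).astype(float) * h
    target_total = target_in_degree * n

    def gap(b: float) -> float:
        return float(_pair_expected_ties(b, same, m).sum()) - target_total

    return brentq(gap, -20.0, 5.0, xtol=1e-10)


def _sample_dyads(
    rng: np.random.Generator, n: int, b: float, h: float, m: float, groups: np.ndarray
) -> np.ndarray:
    """Sample a directed adjacency matrix from the paired-dyad model."""
    iu, ju = np.triu_indices(n, k=1)
    a = b + h * (groups[iu] == groups[ju]).astype(float)
    e1 = np.exp(a)
    e2 = np.exp(2.0 * a + m)
    z = 1.0 + 2.0 * e1 + e2
    # outcomes: 0 none, 1 i->j only, 2 j->i only, 3 mutual
    p = np.column_stack([np.ones_like(e1), e1, e1, e2]) / z[:, None]
    u = rng.random(len(iu))
    cum = np.cumsum(p, axis=1)
    outcome = (u[:, None] > cum).sum(axis=1)
    adj = np.zeros((n, n), dtype=np.int8)
    fwd = (outcome == 1) | (outcome == 3)
    bwd = (outcome == 2) | (outcome == 3)
    adj[iu[fwd], ju[fwd]] = 1
    adj[ju[bwd], iu[bwd]] = 1
    return adj


def _directed_tie_prob(b: float, h_same: np.ndarray, m: float) -> np.ndarray:
    """Marginal probability of one directed tie under the paired-dyad model."""
    a = b + h_same
    e1 = np.exp(a)
    e2 = np.exp(2.0 * a + m)
    return (e1 + e2) / (1.0 + 2.0 * e1 + e2)


def _truncate_out_degree(
    adj: np.ndarray, cap: int, rng: np.random.Generator
) -> np.ndarray:
    out = adj.sum(axis=1)
    for i in np.nonzero(out > cap)[0]:
        alters = np.nonzero(adj[i])[0]
        drop = rng.choice(alters, size=len(alters) - cap, replace=False)
        adj[i, drop] = 0
    return adj


# --------------------------------------------------------------------------
# attributes and items

_AGE_CATS = ("11", "12", "13", "14", "15+")
_PSYCHOSOCIAL = (
    "self_efficacy",
    "need_to_belong",
    "fear_negative_evaluation",
    "prosocial_behavior",
    "openness",
    "extraversion",
    "agreeableness",
    "conscientiousness",
    "emotional_stability",
)


def _draw_attributes(
    rng: np.random.Generator, n: int, groups_t0: np.ndarray
) -> pd.DataFrame:
    favorable = np.isin(groups_t0, list(FAVORABLE_GROUPS))
    # favorable-group students skew slightly older
    base_age = np.array([0.06, 0.44, 0.40, 0.08, 0.02])
    old_age = np.array([0.02, 0.30, 0.45, 0.17, 0.06])
    age = np.array(
        [
            rng.choice(_AGE_CATS, p=old_age if f else base_age)
            for f in favorable
        ]
    )
    sex = rng.choice(["girl", "boy", "prefer-not-say"], size=n, p=[0.49, 0.49, 0.02])
    home = rng.choice(
        ["single parent", "both parents", "other adults"], size=n, p=[0.20, 0.70, 0.10]
    )
    ethnic = rng.random(n) < 0.15
    frame = pd.DataFrame(
        {
            "age_category": age,
            "sex": sex,
            "home_composition": home,
            "ethnic_minority": ethnic.astype(int),
        }
    )
    for scale in _PSYCHOSOCIAL:
        vals = rng.normal(0.60, 0.15, size=n)
        if scale == "self_efficacy":  # favorable groups a touch less self-efficacious
            vals -= 0.08 * favorable
        frame[scale] = np.clip(vals, 0.0, 1.0).round(3)
    return frame


def _draw_items(
    rng: np.random.Generator,
    groups: np.ndarray,
    wave: str,
    means: dict,
    item_sd: float,
    student_sd: float,
) -> pd.DataFrame:
    """Raw Likert items around the group means on the standardized scale."""
    n = len(groups)
    desc_mu = np.array([means[g][0] for g in groups])
    inj_mu = np.array([means[g][1] for g in groups])
    # a per-student trait deviation shared across a wave's items makes items
    # within a scale positively correlated, as real psychometric items are
    desc_mu = desc_mu + rng.normal(0.0, student_sd, size=n)
    inj_mu = inj_mu + rng.normal(0.0, student_sd, size=n)
    cols = {}
    for fam in ITEM_FAMILIES:
        mu = desc_mu if fam.kind == "descriptive" else inj_mu
        u = mu[:, None] + rng.normal(0.0, item_sd, size=(n, fam.n_items))
        u = np.clip(u, 0.0, 1.0)
        if not fam.high_is_favorable:
            u = 1.0 - u
        raw = np.rint(fam.scale_min + u * (fam.scale_max - fam.scale_min))
        for k, name in enumerate(item_columns(fam, wave)):
            cols[name] = raw[:, k].astype(float)
    return pd.DataFrame(cols)


# --------------------------------------------------------------------------
# public operations


def generate_school(
    config: CohortConfig, school_index: int
) -> tuple[pd.DataFrame, TwoWaveNetwork]:
    """Generate one school's student table and two-wave friendship network.

    Returns the long attribute table (one row per student x wave, including
    raw norm items and the planted ``true_group``) and the network.
    """
    seed_seq = np.random.SeedSequence(config.seed).spawn(config.n_schools)[school_index]
    rng = np.random.default_rng(seed_seq)
    lo, hi = config.school_size_range
    n = int(rng.integers(lo, hi + 1))
    school = config.school_name(school_index)
    setting = config.setting_of(school_index)
    intervention = config.intervention_of(school_index)

    prev = np.asarray(config.group_prevalence, dtype=float)
    groups_t0 = rng.choice(GROUPS, size=n, p=prev)

    # baseline ties
    h, m = config.homophily_strength, config.mutuality_strength
    b = _calibrate_base_rate(groups_t0, config.target_in_degree, h, m)
    adj0 = _sample_dyads(rng, n, b, h, m, groups_t0)
    adj0 = _truncate_out_degree(adj0, config.max_nominations, rng)

    # follow-up group: favorable/against transition with peer influence
    favorable0 = np.isin(groups_t0, list(FAVORABLE_GROUPS))
    n_fav_friends = adj0 @ favorable0.astype(float)
    lo_base = np.where(
        favorable0, logit(P_STAY_FAVORABLE), logit(P_BECOME_FAVORABLE)
    )
    shift = config.influence_strength * n_fav_friends
    if intervention == "peer-led":
        shift = shift - config.intervention_effect
    p_fav1 = expit(lo_base + shift)
    favorable1 = rng.random(n) < p_fav1
    p_group1 = prev[0] / (prev[0] + prev[2])
    new_fav_group = np.where(rng.random(n) < p_group1, 1, 3)
    groups_t1 = np.where(
        favorable1, np.where(favorable0, groups_t0, new_fav_group), 2
    ).astype(int)

    # follow-up ties: persistence plus calibrated new-tie draws; reciprocated
    # baseline ties persist longer and new ties preferentially reciprocate
    # kept ties, planting the reciprocity the dissolution/formation models
    # are meant to detect
    rho = config.tie_persistence
    n_ties0 = int(adj0.sum())
    if rho >= 1.0 or rho <= 0.0 or n_ties0 == 0:
        adj1 = (adj0 * int(rho >= 1.0)).astype(np.int8)
    else:
        m_diss = config.dissolution_reciprocity
        recip = (adj0 & adj0.T).astype(float)
        recip_frac = float(recip.sum() / n_ties0)
        keep_logit = logit(rho) + m_diss * (recip - recip_frac)
        keep = rng.random(adj0.shape) < expit(keep_logit)
        adj1 = (adj0 & keep).astype(np.int8)
        empty = (adj0 == 0) & ~np.eye(n, dtype=bool)
        same = (groups_t0[:, None] == groups_t0[None, :]).astype(float) * h
        p_dir = _directed_tie_prob(b, same, m)
        boost = np.exp(config.formation_reciprocity * adj1.T)
        weight = p_dir * boost
        total_w_empty = float(weight[empty].sum())
        if total_w_empty > 0:
            scale = (1.0 - rho) * n_ties0 / total_w_empty
            q = np.clip(weight * scale, 0.0, 1.0)
            new = empty & (rng.random(adj0.shape) < q)
            adj1 = (adj1 | new).astype(np.int8)
    adj1 = _truncate_out_degree(adj1, config.max_nominations, rng)

    students = [f"{school}-s{i + 1:03d}" for i in range(n)]
    attrs = _draw_attributes(rng, n, groups_t0)
    n_peer_sup = int(round(0.18 * n)) if intervention == "peer-led" else 0
    peer_sup = np.zeros(n, dtype=int)
    if n_peer_sup:
        peer_sup[rng.choice(n, size=n_peer_sup, replace=False)] = 1

    rows = []
    for wave, groups_w in zip(WAVES, (groups_t0, groups_t1)):
        frame = attrs.copy()
        frame.insert(0, "school", school)
        frame.insert(1, "student", students)
        frame.insert(2, "wave", wave)
        frame["setting"] = setting
        frame["intervention"] = intervention
        frame["peer_supporter"] = peer_sup
        frame["true_group"] = groups_w
        items = _draw_items(
            rng,
            groups_w,
            wave,
            config.norm_group_means,
            config.item_noise_sd,
            config.student_noise_sd,
        )
        rows.append(pd.concat([frame, items], axis=1))
    table = validate_student_table(pd.concat(rows, ignore_index=True))

    idx = {i: s for i, s in enumerate(students)}
    ties0 = frozenset((idx[i], idx[j]) for i, j in zip(*np.nonzero(adj0)))
    ties1 = frozenset((idx[i], idx[j]) for i, j in zip(*np.nonzero(adj1)))
    network = TwoWaveNetwork(tuple(students), ties0, ties1, school=school)
    return table, network


def generate_study(config: CohortConfig) -> list[tuple[pd.DataFrame, TwoWaveNetwork]]:
    """Generate the full multi-school study; deterministic under the seed."""
    return [generate_school(config, k) for k in range(config.n_schools)]


def inject_missingness(
    table: pd.DataFrame, rate: float, seed: int
) -> pd.DataFrame:
    """Blank the norm items of a random fraction of students in one wave.

    Each selected student loses all raw norm items at one randomly chosen
    wave, so complete-case filtering downstream drops them, mirroring a study
    where only a subset of participants has complete two-wave norm data.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    students = out[["school", "student"]].drop_duplicates()
    hit = rng.random(len(students)) < rate
    hit_waves = rng.choice(WAVES, size=len(students))
    item_cols = [
        c
        for c in out.columns
        if any(c.startswith(f"{fam.name}_") for fam in ITEM_FAMILIES)
    ]
    for (_, row), h, w in zip(students.iterrows(), hit, hit_waves):
        if not h:
            continue
        mask = (
            (out["school"] == row["school"])
            & (out["student"] == row["student"])
            & (out["wave"] == w)
        )
        out.loc[mask, item_cols] = np.nan
    return out
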