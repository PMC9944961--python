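"""Core containers shared across the pipeline.

The study design these containers encode: students in a school year group
nominate up to ten of their closest friends at two measurement waves
(baseline, before a smoking-prevention intervention, and follow-up after it).
Alongside the nominations each student answers self-report and incentivized
survey items measuring descriptive norms (beliefs about what others do) and
injunctive norms (beliefs about what others approve of) around smoking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: canonical wave labels
WAVES = ("baseline", "followup")

#: latent norm groups: 1 = descriptive norms favorable toward smoking,
#: 2 = both norms against smoking, 3 = injunctive norms favorable.
GROUPS = (1, 2, 3)

#: groups on the "favorable toward smoking" side of the dichotomy used by
#: the transition and influence analyses (group 2 is the "against" side).
FAVORABLE_GROUPS = frozenset({1, 3})


def side_of_group(group: int) -> str:
    """Collapse a three-level norm group to the favorable/against dichotomy."""
    return "favorable" if group in FAVORABLE_GROUPS else "against"


@dataclass(frozen=True)
class ItemFamily:
    """Declaration of one block of Likert norm items.

    ``high_is_favorable`` records the direction of the raw coding: True when
    the top of the raw scale means "favorable toward smoking".
    """

    name: str
    kind: str  # "descriptive" | "injunctive"
    n_items: int
    scale_min: int
    scale_max: int
    high_is_favorable: bool


#: The item inventory emulated by the synthetic cohort: a 7-item self-report
#: injunctive scale (1-5, top = definitely should not smoke), family and peer
#: descriptive scales (1-6, top = never smokes), an 8-item incentivized
#: injunctive block (1-6, top = socially appropriate) and a 2-item
#: incentivized descriptive block (1-6, top = all peers accepting).
ITEM_FAMILIES = (
    ItemFamily("sr_injunctive", "injunctive", 7, 1, 5, high_is_favorable=False),
    ItemFamily("sr_descriptive_family", "descriptive", 5, 1, 6, high_is_favorable=False),
    ItemFamily("sr_descriptive_peer", "descriptive", 3, 1, 6, high_is_favorable=False),
    ItemFamily("inc_injunctive", "injunctive", 8, 1, 6, high_is_favorable=True),
    ItemFamily("inc_descriptive", "descriptive", 2, 1, 6, high_is_favorable=True),
)

#: Within the incentivized injunctive block, items aggregate into four
#: scenario groups: peer influence (4 items), smoke-free environment (2),
#: control of supply (1) and control of advertising (1).
INC_INJUNCTIVE_SUBGROUPS = {
    "inc_inj_peer": (0, 1, 2, 3),
    "inc_inj_smokefree": (4, 5),
    "inc_inj_supply": (6,),
    "inc_inj_advertising": (7,),
}


def item_columns(family: ItemFamily, wave: str) -> list[str]:
    """Column names used for a family's raw items at one wave."""
    return [f"{family.name}_{wave}_{k + 1}" for k in range(family.n_items)]


def all_item_columns() -> list[str]:
    cols: list[str] = []
    for wave in WAVES:
        for fam in ITEM_FAMILIES:
            cols.extend(item_columns(fam, wave))
    return cols


@dataclass
class TwoWaveNetwork:
    """Directed friendship nominations observed at two waves on one roster.

    Ties are ordered (ego, alter) pairs; self-nominations are invalid and the
    out-degree at each wave is capped by the nomination limit of the survey
    instrument.
    """

    roster: tuple
    ties_t0: frozenset
    ties_t1: frozenset
    school: str = "school"
    wave_labels: tuple = WAVES

    def __post_init__(self) -> None:
        self.roster = tuple(self.roster)
        self.ties_t0 = frozenset(map(tuple, self.ties_t0))
        self.ties_t1 = frozenset(map(tuple, self.ties_t1))
        members = set(self.roster)
        for label, ties in (("baseline", self.ties_t0), ("followup", self.ties_t1)):
            for ego, alter in ties:
                if ego == alter:
                    raise ValueError(f"self-nomination {ego!r} in {label} wave")
                if ego not in members or alter not in members:
                    raise ValueError(
                        f"tie ({ego!r}, {alter!r}) in {label} wave has an "
                        "endpoint outside the roster"
                    )

    def ties(self, wave: str) -> frozenset:
        if wave == self.wave_labels[0]:
            return self.ties_t0
        if wave == self.wave_labels[1]:
            return self.ties_t1
        raise KeyError(wave)

    def adjacency(self, wave: str) -> np.ndarray:
        """Dense 0/1 adjacency in roster order."""
        index = {s: i for i, s in enumerate(self.roster)}
        a = np.zeros((len(self.roster), len(self.roster)), dtype=np.int8)
        for ego, alter in self.ties(wave):
            a[index[ego], index[alter]] = 1
        return a


def validate_student_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long (one row per student x wave) attribute table."""
    required = {"school", "student", "wave"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"attribute table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["school", "student", "wave"]).sum()
    if dup:
        raise ValueError(f"{dup} duplicated (school, student, wave) rows")
    bad_wave = set(table["wave"]) - set(WAVES)
    if bad_wave:
        raise ValueError(f"unknown wave labels: {sorted(bad_wave)}")
    if "true_group" in table.columns:
        groups = table["true_group"].dropna()
        if not groups.isin(GROUPS).all():
            raise ValueError("true_group labels must be in {1, 2, 3}")
    return table
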