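"""Two-wave network bookkeeping and structural-change metrics.

Quantifies how a directed friendship network changed between baseline and
follow-up: per-wave size, tie count, mean in-degree and density, plus the
Jaccard tie-change index

    J = A11 / (A01 + A11 + A10)

over ordered pairs, where A11 counts ties present at both waves, A01 ties
present only at follow-up, and A10 ties present only at baseline. Values in
the [0.3, 0.6] band indicate gradual structural change: enough turnover to
study tie dynamics, not so much that the waves are unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import WAVES, TwoWaveNetwork

__all__ = [
    "TieChangeCounts",
    "NetworkSummary",
    "align_waves",
    "summarize_network",
    "jaccard_change",
    "classify_change",
    "network_table",
]

#: inclusive endpoints of the gradual-change band for the Jaccard index
GRADUAL_BAND = (0.3, 0.6)


@dataclass(frozen=True)
class TieChangeCounts:
    a11: int  # ties present at both waves
    a01: int  # ties only at follow-up
    a10: int  # ties only at baseline

    @property
    def jaccard(self) -> float:
        denom = self.a11 + self.a01 + self.a10
        if denom == 0:
            raise ValueError("Jaccard undefined: both waves have no ties")
        return self.a11 / denom


@dataclass(frozen=True)
class NetworkSummary:
    nodes: int
    ties: int

    @property
    def mean_in_degree(self) -> float:
        return self.ties / self.nodes

    @property
    def density(self) -> float:
        return self.ties / (self.nodes * (self.nodes - 1))


def align_waves(
    net_t0_roster,
    ties_t0,
    net_t1_roster,
    ties_t1,
    policy: str = "intersection",
    school: str = "school",
) -> TwoWaveNetwork:
    """Put two single-wave observations on a common roster.

    ``intersection`` (default) restricts change metrics to students present
    at both waves; ``union`` keeps everyone, so ties of leavers/joiners count
    as dissolved/newly formed.
    """
    s0, s1 = set(net_t0_roster), set(net_t1_roster)
    if policy == "intersection":
        shared = s0 & s1
        if not shared:
            raise ValueError("wave rosters share no students")
    elif policy == "union":
        shared = s0 | s1
    else:
        raise ValueError(f"unknown alignment policy {policy!r}")
    keep0 = {t for t in ties_t0 if t[0] in shared and t[1] in shared}
    keep1 = {t for t in ties_t1 if t[0] in shared and t[1] in shared}
    return TwoWaveNetwork(tuple(sorted(shared)), keep0, keep1, school=school)


def summarize_network(n_nodes: int, ties) -> NetworkSummary:
    """Per-wave summary; ``ties`` may be a tie set or a tie count."""
    if n_nodes < 2:
        raise ValueError("density undefined for networks of fewer than 2 nodes")
    n_ties = ties if isinstance(ties, int) else len(ties)
    return NetworkSummary(nodes=n_nodes, ties=n_ties)


def jaccard_change(two_wave: TwoWaveNetwork) -> TieChangeCounts:
    t0, t1 = two_wave.ties_t0, two_wave.ties_t1
    counts = TieChangeCounts(
        a11=len(t0 & t1), a01=len(t1 - t0), a10=len(t0 - t1)
    )
    counts.jaccard  # raise early if undefined
    return counts


def classify_change(j: float) -> str:
    if not 0.0 <= j <= 1.0:
        raise ValueError("Jaccard index must lie in [0, 1]")
    lo, hi = GRADUAL_BAND
    if j < lo:
        return "below-band"
    if j > hi:
        return "above-band"
    return "gradual-change band"


def network_table(networks: list[TwoWaveNetwork]) -> pd.DataFrame:
    """Per school x wave summary plus the per-school Jaccard index.

    Display rounding follows the reporting convention for such tables:
    1 decimal for mean in-degree, 2 for density and the Jaccard index.
    """
    rows = []
    for net in networks:
        counts = jaccard_change(net)
        for wave in WAVES:
            s = summarize_network(len(net.roster), net.ties(wave))
            rows.append(
                {
                    "school": net.school,
                    "wave": wave,
                    "nodes": s.nodes,
                    "ties": s.ties,
                    "mean_in_degree": round(s.mean_in_degree, 1),
                    "density": round(s.density, 2),
                    "jaccard": round(counts.jaccard, 2) if wave == WAVES[0] else "",
                    "change_band": classify_change(counts.jaccard)
                    if wave == WAVES[0]
                    else "",
                }
            )
    return pd.DataFrame(rows)
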