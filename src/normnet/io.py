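"""Reading and writing the pipeline's file formats.

Formats are deliberately plain: a long attributes CSV (one row per
student x wave), an edge-list CSV with header ``school,wave,ego,alter``,
per-stage result CSVs, and optional GraphML exports of each school x wave.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .data import WAVES, TwoWaveNetwork, validate_student_table

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["school", "wave", "ego", "alter"]


def write_edges_csv(networks: list[TwoWaveNetwork], path: str | Path) -> None:
    rows = []
    for net in networks:
        for wave in WAVES:
            for ego, alter in sorted(net.ties(wave)):
                rows.append((net.school, wave, ego, alter))
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, index=False)


def write_attributes_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_attributes_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    try:
        return validate_student_table(table)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def read_edges_csv(path: str | Path, rosters: dict | None = None) -> list[TwoWaveNetwork]:
    """Load two-wave networks from an edge-list CSV.

    Self-nominations are dropped and duplicated ties deduplicated, each with
    a logged count. ``rosters`` (school -> iterable of ids) extends the node
    set beyond students appearing in some tie; by default the roster is the
    union of endpoints over both waves.
    """
    frame = pd.read_csv(path)
    missing = set(EDGE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: edge list missing columns {sorted(missing)}")
    bad_wave = set(frame["wave"]) - set(WAVES)
    if bad_wave:
        raise ValueError(f"{path}: unknown wave labels {sorted(bad_wave)}")

    self_loops = int((frame["ego"] == frame["alter"]).sum())
    if self_loops:
        log.warning("dropping %d self-nominations", self_loops)
        frame = frame[frame["ego"] != frame["alter"]]
    n_before = len(frame)
    frame = frame.drop_duplicates(subset=EDGE_COLUMNS)
    if len(frame) < n_before:
        log.warning("deduplicated %d repeated ties", n_before - len(frame))

    networks = []
    for school, sub in frame.groupby("school", sort=True):
        ties = {
            wave: frozenset(
                zip(sub.loc[sub["wave"] == wave, "ego"],
                    sub.loc[sub["wave"] == wave, "alter"])
            )
            for wave in WAVES
        }
        if rosters is not None and school in rosters:
            roster = tuple(rosters[school])
        else:
            nodes = set()
            for tset in ties.values():
                for e, a in tset:
                    nodes.update((e, a))
            roster = tuple(sorted(nodes))
        networks.append(
            TwoWaveNetwork(roster, ties[WAVES[0]], ties[WAVES[1]], school=school)
        )
    return networks


def rosters_from_attributes(table: pd.DataFrame) -> dict:
    return {
        school: tuple(sorted(sub["student"].unique()))
        for school, sub in table.groupby("school", sort=True)
    }


def write_graphml(net: TwoWaveNetwork, wave: str, path: str | Path) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(net.roster)
    g.add_edges_from(net.ties(wave))
    nx.write_graphml(g, path)
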