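"""Build undirected friendship / borrow-lend / overlap layers from tie tables.

Ties come from survey name generators.  A friendship edge exists when at
least one member of a dyad nominates the other under any friendship
generator; a borrow/lend edge when either nominates the other as a
trusted borrowing or lending partner.  Nominations within a household
and nominations of persons absent from the analyzable roster are
dropped.  All layers are simple undirected graphs over the full roster,
so persons without ties remain as isolated nodes with zero censuses.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "FRIENDSHIP_GENERATORS",
    "BORROW_LEND_GENERATORS",
    "LayeredVillageGraph",
    "build_layers",
    "tie_overlap_summary",
    "overlap_shares",
]

FRIENDSHIP_GENERATORS = ("closest_friend", "free_time", "personal_private")
BORROW_LEND_GENERATORS = ("borrow_money", "lend_money")
KNOWN_GENERATORS = FRIENDSHIP_GENERATORS + BORROW_LEND_GENERATORS + ("other",)

LAYERS = ("friendship", "borrow_lend", "overlap")


@dataclass
class LayeredVillageGraph:
    """Per-layer undirected simple graphs for one village-wave."""

    village_id: str
    wave: int
    layers: dict[str, nx.Graph]

    def __getitem__(self, layer: str) -> nx.Graph:
        return self.layers[layer]


def build_layers(
    ties: pd.DataFrame,
    roster: pd.DataFrame,
    wave: int,
    friendship_generators: tuple[str, ...] = FRIENDSHIP_GENERATORS,
) -> LayeredVillageGraph:
    """Construct friendship, borrow/lend, and overlap layers for one village-wave.

    Parameters
    ----------
    ties : DataFrame with columns ego_id, alter_id, generator, wave
    roster : DataFrame with columns person_id, household_id (one village-wave)
    wave : survey wave to build (1 or 2)
    """
    if roster.empty:
        raise ValueError("empty roster: no analyzable persons for this village-wave")
    known = set(friendship_generators) | set(BORROW_LEND_GENERATORS) | {"other"}
    unknown = set(ties["generator"].unique()) - known
    if unknown:
        raise ValueError(f"unknown name-generator label(s): {sorted(unknown)}")

    persons = roster["person_id"].astype(str)
    household = dict(zip(persons, roster["household_id"].astype(str)))
    node_set = set(persons)

    t = ties.loc[ties["wave"] == wave].copy()
    t["ego_id"] = t["ego_id"].astype(str)
    t["alter_id"] = t["alter_id"].astype(str)
    # drop self-nominations, nominations outside the roster, within-household
    t = t[t["ego_id"] != t["alter_id"]]
    t = t[t["ego_id"].isin(node_set) & t["alter_id"].isin(node_set)]
    same_hh = t["ego_id"].map(household) == t["alter_id"].map(household)
    t = t[~same_hh]

    def edge_set(generators: tuple[str, ...]) -> set[tuple[str, str]]:
        sub = t[t["generator"].isin(generators)]
        return {
            (a, b) if a < b else (b, a)
            for a, b in zip(sub["ego_id"], sub["alter_id"])
        }

    f_edges = edge_set(friendship_generators)
    b_edges = edge_set(BORROW_LEND_GENERATORS)

    village_id = str(roster["village_id"].iloc[0]) if "village_id" in roster else ""
    layers = {}
    for name, edges in (
        ("friendship", f_edges),
        ("borrow_lend", b_edges),
        ("overlap", f_edges & b_edges),
    ):
        g = nx.Graph()
        g.add_nodes_from(node_set)
        g.add_edges_from(edges)
        layers[name] = g
    return LayeredVillageGraph(village_id=village_id, wave=wave, layers=layers)


def overlap_shares(n_friendship: int, n_borrow_lend: int, n_shared: int) -> dict[str, float]:
    """Overlap percentages from raw tie counts, rounded to 2 dp for reporting.

    Returns the shared count as a percentage of the borrow/lend volume,
    of the friendship volume, and of the union (combined) volume.  Empty
    layers give 0 rather than a division error.
    """
    n_union = n_friendship + n_borrow_lend - n_shared

    def pct(num: int, den: int) -> float:
        return round(100.0 * num / den, 2) if den else 0.0

    return {
        "n_friendship": n_friendship,
        "n_borrow_lend": n_borrow_lend,
        "n_shared": n_shared,
        "n_union": n_union,
        "pct_of_borrow_lend": pct(n_shared, n_borrow_lend),
        "pct_of_friendship": pct(n_shared, n_friendship),
        "pct_of_union": pct(n_shared, n_union),
    }


def tie_overlap_summary(graphs) -> pd.DataFrame:
    """Tie-overlap accounting for one LayeredVillageGraph or a collection.

    In pooled mode (a list), counts are summed over villages and waves
    *before* dividing, matching cohort-level reporting.
    """
    if isinstance(graphs, LayeredVillageGraph):
        graphs = [graphs]
    nf = nb = ns = 0
    for g in graphs:
        f = set(frozenset(e) for e in g["friendship"].edges())
        b = set(frozenset(e) for e in g["borrow_lend"].edges())
        nf += len(f)
        nb += len(b)
        ns += len(f & b)
    return pd.DataFrame([overlap_shares(nf, nb, ns)])
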