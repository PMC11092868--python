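"""Network-pathway integration.

Projects the interaction collection onto curated biosystem gene sets: a
binary membership matrix, per-biosystem graph distance from the bait (with
and without the experimental direct edges), the backing table of a
protein-biosystem cord diagram, and a shared-biosystem prioritization score
that ranks collection members by how many (optionally relevance-weighted)
biosystems they share with the bait.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .quant import CandidateSet
from .landscape import InteractionGraph, LevelAssignment, assign_levels

__all__ = [
    "PathwayAnnotation",
    "membership_matrix",
    "biosystem_distance",
    "build_cord_table",
    "prioritize_targets",
]

logger = logging.getLogger(__name__)

RELEVANCE_TAGS = ("FXN-function", "mitochondrial-biology", "FRDA-pathogenesis")


@dataclass
class PathwayAnnotation:
    """Named biosystem gene sets with optional relevance tags.

    ``biosystems`` is an ordered list of (name, description, member set);
    ``tags`` maps biosystem names to a relevance tag (bait function,
    mitochondrial biology, disease pathogenesis).
    """

    biosystems: list
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [n for n, _, _ in self.biosystems]
        if len(names) != len(set(names)):
            raise ValueError("biosystem names must be unique")
        for name, _, members in self.biosystems:
            if not members:
                raise ValueError(f"biosystem {name!r} has no members")
        unknown = set(self.tags.values()) - set(RELEVANCE_TAGS)
        if unknown:
            raise ValueError(f"unknown relevance tags: {sorted(unknown)}")

    @property
    def names(self) -> list:
        return [n for n, _, _ in self.biosystems]

    def members(self, name: str) -> set:
        for n, _, m in self.biosystems:
            if n == name:
                return m
        raise KeyError(name)


def _in_biosystem(members: set, accession: str, gene_symbol: str) -> bool:
    if accession in members:
        return True
    fold = {str(m).casefold() for m in members}
    return str(gene_symbol).casefold() in fold


def membership_matrix(
    collection: CandidateSet, ann: PathwayAnnotation, bait: str
) -> pd.DataFrame:
    """Binary protein x biosystem matrix; the bait is an extra row."""
    index = [bait] + sorted(collection.protein_ids)
    sym = dict(zip(collection.df["protein_id"], collection.df["gene_symbol"]))
    data = {}
    for name, _, members in ann.biosystems:
        col = []
        for pid in index:
            gs = sym.get(pid, pid)
            col.append(1 if _in_biosystem(members, pid, gs) else 0)
        data[name] = col
    return pd.DataFrame(data, index=index)


def biosystem_distance(
    g_db: InteractionGraph,
    ann: PathwayAnnotation,
    collection: CandidateSet | None = None,
) -> pd.DataFrame:
    """Minimum bait distance of each biosystem, before and after the experiment.

    distance(biosystem) = min over member proteins present in the graph of
    their BFS level.  Computed on the database-only graph and, when a
    collection is supplied, on the graph augmented with one experimental
    direct edge bait-m per collection member; the delta shows how the
    experiment shortens pathway distance from the bait.  Biosystems with no
    member in the graph report an infinite distance with a warning.
    """
    levels_db = assign_levels(g_db)

    levels_aug: LevelAssignment | None = None
    if collection is not None:
        g_aug = InteractionGraph(g=g_db.g.copy(), bait=g_db.bait, aliases=g_db.aliases)
        for _, row in collection.df.iterrows():
            node = g_db.resolve(str(row["protein_id"])) or g_db.resolve(str(row["gene_symbol"]))
            if node is not None and node != g_db.bait:
                if not g_aug.g.has_edge(g_db.bait, node, key="physical"):
                    g_aug.g.add_edge(g_db.bait, node, key="physical",
                                     sources={"experimental"})
        levels_aug = assign_levels(g_aug)

    def biodist(levels: LevelAssignment, members: set) -> float:
        present = []
        for m in members:
            node = g_db.resolve(str(m))
            if node is not None:
                present.append(levels.level(node))
        return min(present) if present else math.inf

    rows = []
    for name, _, members in ann.biosystems:
        d_db = biodist(levels_db, members)
        if d_db == math.inf:
            logger.warning("biosystem %r has no member in the graph", name)
        if levels_aug is not None:
            d_aug = biodist(levels_aug, members)
            delta = d_db - d_aug if math.inf not in (d_db, d_aug) else math.nan
        else:
            d_aug, delta = math.nan, math.nan
        rows.append((name, d_db, d_aug, delta))
    return pd.DataFrame(rows, columns=["biosystem", "distance_db", "distance_with_experiment", "delta"])


def build_cord_table(
    collection: CandidateSet,
    levels: LevelAssignment,
    novelty: pd.DataFrame,
    ann: PathwayAnnotation,
    graph: InteractionGraph | None = None,
) -> tuple[pd.DataFrame, list]:
    """Backing table of the protein-biosystem cord diagram.

    One row per (member, biosystem) membership pair carrying the member's
    database level, novelty call and the edge type(s) of the first hop of
    its witness path.  Members belonging to no biosystem are returned in a
    side list.  Row count equals the number of 1-entries of the membership
    matrix restricted to the collection.
    """
    nov = novelty.set_index("protein_id") if len(novelty) else pd.DataFrame()
    rows, unannotated = [], []
    for _, member in collection.df.sort_values("protein_id").iterrows():
        pid, sym = str(member["protein_id"]), str(member["gene_symbol"])
        hit_any = False
        level = math.inf
        call = "unconnected"
        first_hop_types = ""
        if len(nov) and pid in nov.index:
            level = nov.loc[pid, "database_level"]
            call = nov.loc[pid, "call"]
            node = nov.loc[pid, "node"]
            if node is not None and node in levels.witness_paths and levels.witness_paths[node]:
                path = levels.witness_paths[node]
                if len(path) >= 2 and graph is not None:
                    first_hop_types = ";".join(sorted(graph.edge_types(path[0], path[1])))
        for name, _, members in ann.biosystems:
            if _in_biosystem(members, pid, sym):
                hit_any = True
                rows.append((pid, name, first_hop_types, level, call))
        if not hit_any:
            unannotated.append(pid)
    df = pd.DataFrame(
        rows,
        columns=["protein_id", "biosystem", "first_hop_types", "database_level", "call"],
    )
    return df, unannotated


def prioritize_targets(
    matrix: pd.DataFrame,
    bait: str,
    tags: dict | None = None,
    weights: dict | None = None,
) -> pd.DataFrame:
    """Rank collection members by relevance-weighted biosystems shared with the bait.

    score(m) = sum over biosystems containing both m and the bait of the
    weight of the biosystem's relevance tag (default weight 1, untagged
    biosystems included at weight 1).  Descending score, ties broken
    lexicographically by protein identifier.
    """
    if bait not in matrix.index:
        raise ValueError(f"bait row {bait!r} missing from the membership matrix")
    tags = tags or {}
    weights = weights or {}
    bait_row = matrix.loc[bait]
    w = pd.Series(
        [weights.get(tags.get(name), 1.0) for name in matrix.columns],
        index=matrix.columns,
    )
    shared = matrix.drop(index=bait).mul(bait_row, axis=1)
    scores = shared.mul(w, axis=1).sum(axis=1)
    out = scores.rename("score").reset_index().rename(columns={"index": "protein_id"})
    out = out.sort_values(["score", "protein_id"], ascending=[False, True]).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out
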