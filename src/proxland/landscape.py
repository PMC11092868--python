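"""Bait-centered interaction landscape: levels, diameter, novelty, dropout.

The landscape is a typed, undirected multigraph over protein identifiers
with a designated bait node.  Unweighted breadth-first distance from the
bait defines the *level* of every protein: L1 proteins are direct
interactors (Pd), L2-L3 indirect (Pi), and level >= 4 or unreachable
proteins non-proximal — the completion of the published level scheme.  Path
length counts edges, so a chain of seven proteins rooted at the bait has a
landscape diameter of six.

Novelty classification compares the experimentally detected interaction
collection against a database-only graph: a member with a direct database
edge to the bait is a *known* direct interaction; a member the experiment
places in proximity despite a database distance of 2-3 is a *new* direct
interaction (and is also tallied as new-indirect for its database path);
deeper or disconnected members carry explicit flags.  When every database
intermediate on a distance-2 path is itself experimentally undetected, the
member is flagged as an intermediate-dropout case — evidence for a direct
bait contact (the FXN-NFS1-via-ISD11 logic).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .quant import CandidateSet

__all__ = [
    "EDGE_TYPES",
    "InteractionGraph",
    "LevelAssignment",
    "DiameterResult",
    "build_graph",
    "assign_levels",
    "landscape_diameter",
    "classify_novelty",
    "flag_intermediate_dropout",
]

logger = logging.getLogger(__name__)

EDGE_TYPES = (
    "physical",
    "co-expression",
    "co-localization",
    "shared-domain",
    "pathway",
    "genetic",
)

LEVEL_DIRECT = 1
LEVEL_INDIRECT_MAX = 3


class UnreachableTargetError(ValueError):
    pass


@dataclass
class InteractionGraph:
    """Typed undirected multigraph with a designated bait.

    Parallel edges are allowed only with distinct types (the multigraph is
    keyed by type); every edge carries a merged ``sources`` set.  ``aliases``
    maps secondary identifiers (e.g. gene symbols when nodes are accessions)
    onto graph nodes so queries work in either identifier space.
    """

    g: nx.MultiGraph
    bait: str
    aliases: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bait not in self.g:
            raise ValueError(f"bait {self.bait!r} is not a graph node")

    @property
    def nodes(self) -> set:
        return set(self.g.nodes)

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def resolve(self, identifier: str) -> str | None:
        """Map an accession or gene symbol onto a graph node, or None."""
        if identifier in self.g:
            return identifier
        alias = self.aliases.get(identifier)
        if alias is not None and alias in self.g:
            return alias
        return None

    def edge_types(self, a: str, b: str) -> set:
        if not self.g.has_edge(a, b):
            return set()
        return set(self.g[a][b].keys())


def build_graph(
    edge_table: pd.DataFrame,
    bait: str,
    keep_nodes: set | None = None,
    aliases: dict | None = None,
    type_filter: set | None = None,
) -> InteractionGraph:
    """Assemble an :class:`InteractionGraph` from an edge table.

    ``edge_table`` has columns ``id_a, id_b, type`` and optionally
    ``source``.  Edges are symmetrized; duplicate (a, b, type) records are
    collapsed with merged sources; self-loops are dropped with a warning;
    unknown edge types map to ``physical`` with a warning.  When
    ``keep_nodes`` is given the graph is induced on keep_nodes + bait +
    every node lying on a shortest bait-to-member path.  ``type_filter``
    restricts to a subset of edge types (e.g. physical-only views).
    """
    g = nx.MultiGraph()
    g.add_node(bait)
    for idx, row in edge_table.iterrows():
        a, b, etype = str(row["id_a"]), str(row["id_b"]), str(row["type"])
        source = str(row["source"]) if "source" in edge_table.columns else "input"
        if a == b:
            logger.warning("dropping self-loop on %s (row %s)", a, idx)
            continue
        if etype not in EDGE_TYPES:
            logger.warning("unknown edge type %r (row %s); mapped to 'physical'", etype, idx)
            etype = "physical"
        if type_filter is not None and etype not in type_filter:
            continue
        if g.has_edge(a, b, key=etype):
            g[a][b][etype]["sources"].add(source)
        else:
            g.add_edge(a, b, key=etype, sources={source})

    alias_map = {}
    if aliases:
        for k, v in aliases.items():
            alias_map[k] = v
            alias_map.setdefault(v, k)

    if keep_nodes is not None:
        keep = {n for n in keep_nodes if n in g} | {bait}
        missing = set(keep_nodes) - keep
        for m in sorted(missing):
            alias = alias_map.get(m)
            if alias is not None and alias in g:
                keep.add(alias)
            else:
                logger.warning("keep node %r absent from the edge table", m)
        extra = set()
        for k in sorted(keep - {bait}):
            if nx.has_path(g, bait, k):
                for path in nx.all_shortest_paths(g, bait, k):
                    extra.update(path)
        g = g.subgraph(keep | extra).copy()

    return InteractionGraph(g=g, bait=bait, aliases=alias_map)


def _proximity_class(level: float) -> str:
    if level == 0:
        return "bait"
    if level == LEVEL_DIRECT:
        return "direct"
    if level <= LEVEL_INDIRECT_MAX:
        return "indirect"
    return "non-proximal"


@dataclass
class LevelAssignment:
    """Per-node BFS distance from the bait with proximity classes.

    ``level`` is math.inf for unreachable nodes; ``witness_path`` is one
    deterministic shortest path (lexicographic tie-break) whose edge count
    equals the level.
    """

    bait: str
    levels: dict
    classes: dict
    witness_paths: dict

    def level(self, node: str) -> float:
        return self.levels.get(node, math.inf)

    @property
    def df(self) -> pd.DataFrame:
        rows = [
            {"id": n, "level": self.levels[n], "class": self.classes[n],
             "witness_path": ">".join(self.witness_paths[n]) if self.witness_paths[n] else ""}
            for n in sorted(self.levels)
        ]
        return pd.DataFrame(rows, columns=["id", "level", "class", "witness_path"])


def assign_levels(graph: InteractionGraph) -> LevelAssignment:
    """BFS from the bait over all edge types with deterministic witnesses."""
    g, bait = graph.g, graph.bait
    dist = nx.single_source_shortest_path_length(g, bait)
    levels, classes, witness = {}, {}, {}
    for node in g.nodes:
        d = dist.get(node, math.inf)
        levels[node] = d
        classes[node] = _proximity_class(d)
        if d is math.inf or d == math.inf:
            witness[node] = None
        else:
            # walk back choosing the lexicographically smallest predecessor
            path = [node]
            cur = node
            while dist[cur] > 0:
                target_d = dist[cur] - 1
                cur = min(n for n in g.neighbors(cur)
                          if dist.get(n, math.inf) == target_d)
                path.append(cur)
            witness[node] = list(reversed(path))
    return LevelAssignment(bait=bait, levels=levels, classes=classes, witness_paths=witness)


@dataclass
class DiameterResult:
    diameter: int
    target: str
    witness_path: list


def landscape_diameter(
    levels: LevelAssignment,
    targets: set,
    on_unreachable: str = "error",
) -> DiameterResult:
    """Maximum level over ``targets`` plus the arg-max target and its path.

    Unreachable targets raise (listing them) or, with
    ``on_unreachable='inf'``, are reported as an infinite diameter with a
    flag on the result.
    """
    unknown = {t for t in targets if t not in levels.levels}
    unreachable = unknown | {t for t in targets if levels.level(t) == math.inf}
    if unreachable and on_unreachable == "error":
        raise UnreachableTargetError(
            f"targets unreachable from bait: {sorted(unreachable)}"
        )
    reachable = [t for t in targets if t not in unreachable]
    if unreachable:
        worst = min(sorted(unreachable))
        res = DiameterResult(diameter=math.inf, target=worst, witness_path=[])
        res.unreachable = sorted(unreachable)  # type: ignore[attr-defined]
        return res
    if not reachable:
        raise ValueError("no targets supplied")
    dmax = max(levels.level(t) for t in reachable)
    target = min(t for t in reachable if levels.level(t) == dmax)
    return DiameterResult(diameter=int(dmax), target=target,
                          witness_path=levels.witness_paths[target])


CALLS = ("known_direct", "new_direct", "unconnected")


def classify_novelty(
    g_db: InteractionGraph, collection: CandidateSet
) -> tuple[pd.DataFrame, dict]:
    """Classify each collection member against the database-only graph.

    Members are resolved onto graph nodes by accession first, gene symbol
    second.  A direct database edge to the bait gives ``known_direct``;
    database distance 2-3 gives ``new_direct`` (the experiment shortcuts a
    known indirect path; the member also counts toward the new-indirect
    tally); finite distance >= 4 gives ``new_direct`` flagged as lacking
    proximal database support; absent or disconnected members are
    ``unconnected``.

    Returns (per-member table, tally dict).  The result depends only on the
    member set, not on input row order.
    """
    levels = assign_levels(g_db)
    rows = []
    for _, member in collection.df.sort_values("protein_id").iterrows():
        pid, sym = str(member["protein_id"]), str(member["gene_symbol"])
        node = g_db.resolve(pid) or g_db.resolve(sym)
        if node is None:
            logger.warning("collection member %s/%s absent from the database graph", pid, sym)
            rows.append((pid, sym, None, math.inf, "unconnected", "absent_from_graph"))
            continue
        if node == g_db.bait:
            continue
        d = levels.level(node)
        if g_db.g.has_edge(g_db.bait, node):
            rows.append((pid, sym, node, 1, "known_direct", ""))
        elif d in (2, 3):
            rows.append((pid, sym, node, int(d), "new_direct", ""))
        elif d != math.inf:
            rows.append((pid, sym, node, int(d), "new_direct", "no proximal database support"))
        else:
            rows.append((pid, sym, node, math.inf, "unconnected", "disconnected_in_graph"))
    df = pd.DataFrame(
        rows,
        columns=["protein_id", "gene_symbol", "node", "database_level", "call", "flag"],
    )
    tallies = {
        "known_direct": int((df["call"] == "known_direct").sum()),
        "new_direct": int((df["call"] == "new_direct").sum()),
        "new_indirect": int(df["database_level"].isin([2, 3]).sum()),
        "unconnected": int((df["call"] == "unconnected").sum()),
    }
    return df, tallies


def flag_intermediate_dropout(
    g_db: InteractionGraph,
    collection: CandidateSet,
    detected: set,
    novelty: pd.DataFrame | None = None,
) -> list[dict]:
    """Flag distance-2 members whose database intermediates are all undetected.

    ``detected`` is the union of the single-method candidate identifiers
    (accessions and/or gene symbols, any case for symbols).  For every
    ``new_direct`` member at database distance 2, all shortest-path
    intermediates are collected; if none of them was detected by either
    method, a flag proposing a direct bait-member interaction is emitted,
    naming the undetected intermediates.
    """
    if novelty is None:
        novelty, _ = classify_novelty(g_db, collection)
    detected_fold = {str(d).casefold() for d in detected}

    def is_detected(node: str) -> bool:
        cands = {node, g_db.aliases.get(node, node)}
        return any(str(c).casefold() in detected_fold for c in cands)

    flags = []
    sel = novelty[(novelty["call"] == "new_direct") & (novelty["database_level"] == 2)]
    for _, row in sel.iterrows():
        node = row["node"]
        intermediates = sorted({
            p[1] for p in nx.all_shortest_paths(g_db.g, g_db.bait, node)
        })
        if not any(is_detected(i) for i in intermediates):
            flags.append({
                "member": row["protein_id"],
                "node": node,
                "undetected_intermediates": intermediates,
                "reason": (
                    "all database intermediates undetected by either method; "
                    "direct bait interaction hypothesized"
                ),
            })
    return flags
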