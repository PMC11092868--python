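"""Synthetic benchmark generator with planted ground truth.

Every pipeline input is generated here so the downstream stages can be
exercised against a known answer:

* bait and control quantification tables (spectral counts ~ Poisson, LFQ
  ~ log-normal) with planted true interactors at elevated abundance,
  control-enriched contaminants and low-abundance background shared by both
  lines;
* a second-method (co-IP-like) detection list covering the true preys at a
  configurable sensitivity;
* mitochondrial reference lists covering a configurable fraction of the
  planted preys;
* a typed interactome with a planted topology: a bait-anchored chain fixing
  the landscape diameter, bait-intermediate-target triads whose
  intermediates are database-only (never detected experimentally), and
  proximity-biased random noise edges;
* biosystem gene sets in which the bait shares at least two pathways with
  one designated planted target and at most one with every other prey.

The chain members, triad targets and the shared-pathway target form the
planted *skeleton*: they are always present in the second-method list, so
landscape-level properties (diameter, dropout flags, pathway ranking) are
deterministic functions of the topology, while recovery of the full
true-interactor set through the quantitative filters remains stochastic.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .quant import QuantTable, CandidateSet

__all__ = [
    "GraphSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_quant_tables",
    "simulate_coip_candidates",
    "simulate_mito_references",
    "simulate_interactome",
    "simulate_pathways",
]

EDGE_TYPES = (
    "physical",
    "co-expression",
    "co-localization",
    "shared-domain",
    "pathway",
    "genetic",
)


class ConfigurationError(ValueError):
    pass


@dataclass
class GraphSpec:
    """Planted-topology descriptor for the synthetic interactome.

    chain_length
        Number of edges in the bait-anchored chain; downstream landscape
        diameter over the planted members equals this value.
    n_triads
        Number of bait-intermediate-target triads; intermediates are
        database-only nodes, so each triad is an intermediate-dropout case.
    extra_edges_per_node
        Random noise edges drawn per eligible node (proximity-biased, never
        touching the chain interior or triad targets, so the planted
        distances are preserved).
    edge_type_weights
        Sampling weights over the six edge types.
    """

    chain_length: int = 6
    n_triads: int = 3
    extra_edges_per_node: int = 2
    edge_type_weights: dict = field(
        default_factory=lambda: {
            "physical": 0.35,
            "co-expression": 0.25,
            "co-localization": 0.15,
            "shared-domain": 0.10,
            "pathway": 0.10,
            "genetic": 0.05,
        }
    )

    def __post_init__(self) -> None:
        if self.chain_length < 1:
            raise ConfigurationError("graph_spec.chain_length must be >= 1")
        if self.n_triads < 0:
            raise ConfigurationError("graph_spec.n_triads must be >= 0")
        if self.extra_edges_per_node < 0:
            raise ConfigurationError("graph_spec.extra_edges_per_node must be >= 0")
        unknown = set(self.edge_type_weights) - set(EDGE_TYPES)
        if unknown:
            raise ConfigurationError(f"unknown edge types in weights: {sorted(unknown)}")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a single bait line against a matched control: 30
    planted true interactors at 5-fold LFQ enrichment with mean spectral
    count 8 per replicate, 170 low-abundance background proteins shared by
    both lines, 20 control-enriched contaminants, 3 replicates, 10% per-
    replicate dropout of true preys, 90% second-method sensitivity, and 95%
    of true preys on the mitochondrial reference lists.
    """

    n_true_interactors: int = 30
    n_background: int = 170
    n_contaminants: int = 20
    n_replicates: int = 3
    true_enrichment: float = 5.0
    count_rate_true: float = 8.0
    count_rate_background: float = 1.0
    dropout_prob: float = 0.1
    coip_sensitivity: float = 0.9
    coip_background_prob: float = 0.05
    # a minority of true preys leak into the ligase-only control at their
    # base (unenriched) intensity; most are absent there, which is the
    # premise of control subtraction in proximity labeling
    true_control_presence: float = 0.25
    mito_fraction_true: float = 0.95
    mito_fraction_other: float = 0.3
    lfq_sigma: float = 0.2  # log10-scale sd of LFQ noise
    bait_accession: str = "B00001"
    bait_symbol: str = "BAIT"
    graph_spec: GraphSpec = field(default_factory=GraphSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_true_interactors", "n_background", "n_contaminants", "n_replicates"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for f in ("dropout_prob", "coip_sensitivity", "coip_background_prob",
                  "true_control_presence", "mito_fraction_true", "mito_fraction_other"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{f} must be in [0, 1], got {v}")
        if not self.true_enrichment > 1:
            raise ConfigurationError("true_enrichment must be > 1")
        for f in ("count_rate_true", "count_rate_background", "lfq_sigma"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0")
        if isinstance(self.graph_spec, dict):
            self.graph_spec = GraphSpec(**self.graph_spec)
        skeleton = self.graph_spec.chain_length + self.graph_spec.n_triads + 1
        if 0 < self.n_true_interactors < skeleton:
            raise ConfigurationError(
                "n_true_interactors must cover the planted skeleton "
                f"(chain + triad targets + shared target = {skeleton})"
            )


@dataclass
class GroundTruth:
    """Planted answer key.  All identifier sets use accessions.

    ``symbol_of`` maps every generated accession (bait included) to its
    gene-symbol alias; the role sets partition the prey universe.
    """

    bait: str
    true_interactors: set
    background: set
    contaminants: set
    planted_chain: list            # ordered accessions, bait first
    planted_intermediate_triads: list  # (bait, intermediate, target) accessions
    shared_pathway_target: str | None
    intermediates: set
    symbol_of: dict
    biosystem_membership: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_interactors & self.contaminants:
            raise ValueError("true_interactors and contaminants must be disjoint")
        if self.true_interactors & self.background or self.background & self.contaminants:
            raise ValueError("ground-truth role sets must be disjoint")
        if self.planted_chain and self.planted_chain[0] != self.bait:
            raise ValueError("planted_chain must start at the bait")

    @property
    def accession_of(self) -> dict:
        return {sym: acc for acc, sym in self.symbol_of.items()}

    def to_json(self, path) -> None:
        data = asdict(self)
        for k in ("true_interactors", "background", "contaminants", "intermediates"):
            data[k] = sorted(data[k])
        data["planted_intermediate_triads"] = [list(t) for t in self.planted_intermediate_triads]
        data["biosystem_membership"] = {k: sorted(v) for k, v in self.biosystem_membership.items()}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        for k in ("true_interactors", "background", "contaminants", "intermediates"):
            data[k] = set(data[k])
        data["planted_intermediate_triads"] = [tuple(t) for t in data["planted_intermediate_triads"]]
        data["biosystem_membership"] = {k: set(v) for k, v in data["biosystem_membership"].items()}
        return cls(**data)

    @property
    def skeleton(self) -> set:
        """Chain members, triad targets and the shared-pathway target."""
        out = set(self.planted_chain[1:])
        out |= {t for (_, _, t) in self.planted_intermediate_triads}
        if self.shared_pathway_target:
            out.add(self.shared_pathway_target)
        return out


def _make_identifiers(rng: np.random.Generator, n: int) -> list[tuple[str, str]]:
    """Unique (accession, gene-symbol) pairs, UniProt-like / symbol-like."""
    pairs: list[tuple[str, str]] = []
    seen_acc: set[str] = set()
    seen_sym: set[str] = set()
    letters = np.array(list(string.ascii_uppercase))
    digits = np.array(list(string.digits))
    while len(pairs) < n:
        acc = "".join(
            [rng.choice(list("OPQ"))]
            + list(rng.choice(digits, 1))
            + list(rng.choice(np.concatenate([letters, digits]), 3))
            + list(rng.choice(digits, 1))
        )
        sym = "".join(rng.choice(letters, 4)) + str(rng.integers(1, 20))
        if acc in seen_acc or sym in seen_sym:
            continue
        seen_acc.add(acc)
        seen_sym.add(sym)
        pairs.append((acc, sym))
    return pairs


def _lognormal_lfq(rng: np.random.Generator, base: float, sigma: float, n: int) -> np.ndarray:
    return base * 10 ** rng.normal(0.0, sigma, size=n)


def simulate_quant_tables(
    config: SimulationConfig,
) -> tuple[QuantTable, QuantTable, GroundTruth]:
    """Generate bait and control quantification tables plus the answer key.

    True preys carry Poisson(count_rate_true) spectral counts per replicate
    with per-replicate dropout and bait LFQ ~ true_enrichment x their
    control-level base intensity; background appears in both lines at
    comparable low LFQ; contaminants are control-enriched so the fold-change
    filter has true negatives.  The planted chain, triads and shared-pathway
    target are laid out here so the topology generators agree with the
    quantitative ground truth.
    """
    rng = np.random.default_rng([config.seed, 0])
    n_total = config.n_true_interactors + config.n_background + config.n_contaminants
    ids = _make_identifiers(rng, n_total)
    true_ids = ids[: config.n_true_interactors]
    bg_ids = ids[config.n_true_interactors: config.n_true_interactors + config.n_background]
    cont_ids = ids[config.n_true_interactors + config.n_background:]

    gs = config.graph_spec
    chain_accs = [config.bait_accession] + [a for a, _ in true_ids[: gs.chain_length]]
    triad_targets = [a for a, _ in true_ids[gs.chain_length: gs.chain_length + gs.n_triads]]
    shared_idx = gs.chain_length + gs.n_triads
    shared_target = true_ids[shared_idx][0] if config.n_true_interactors > shared_idx else None
    if config.n_true_interactors == 0:
        chain_accs, triad_targets, shared_target = [config.bait_accession], [], None

    symbol_of = {config.bait_accession: config.bait_symbol}
    symbol_of.update({a: s for a, s in ids})

    n = config.n_replicates
    sigma = config.lfq_sigma
    bait_rows, ctrl_rows = [], []

    # intensity scales: shared background dominates total signal (as in real
    # pulldowns, where bait-specific preys are a small fraction of intensity),
    # so total-intensity normalization stays near-neutral between the lines.
    for acc, sym in true_ids:
        base = 10 ** rng.normal(5.5, 0.3)
        counts = rng.poisson(config.count_rate_true, size=n)
        lfq = _lognormal_lfq(rng, base * config.true_enrichment, sigma, n)
        drop = rng.random(n) < config.dropout_prob
        counts = np.where(drop, 0, counts)
        lfq = np.where(drop, 0.0, lfq)
        bait_rows.append((acc, sym, counts, lfq))
        if rng.random() < config.true_control_presence:
            ctrl_rows.append((
                acc, sym,
                rng.poisson(config.count_rate_background, size=n),
                _lognormal_lfq(rng, base, sigma, n),
            ))

    for acc, sym in bg_ids:
        base = 10 ** rng.normal(6.5, 0.3)
        bait_rows.append((
            acc, sym,
            rng.poisson(config.count_rate_background, size=n),
            _lognormal_lfq(rng, base, sigma, n),
        ))
        ctrl_rows.append((
            acc, sym,
            rng.poisson(config.count_rate_background, size=n),
            _lognormal_lfq(rng, base, sigma, n),
        ))

    for acc, sym in cont_ids:
        base = 10 ** rng.normal(6.5, 0.3)
        ratio = rng.uniform(1.0, 3.0)  # control LFQ >= bait LFQ
        bait_rows.append((
            acc, sym,
            rng.poisson(config.count_rate_true, size=n),
            _lognormal_lfq(rng, base / ratio, sigma, n),
        ))
        ctrl_rows.append((
            acc, sym,
            rng.poisson(config.count_rate_true, size=n),
            _lognormal_lfq(rng, base, sigma, n),
        ))

    def _frame(rows):
        recs = []
        for acc, sym, counts, lfq in rows:
            rec = {"protein_id": acc, "gene_symbol": sym}
            rec.update({f"sc_rep{i+1}": int(c) for i, c in enumerate(counts)})
            rec.update({f"lfq_rep{i+1}": float(v) for i, v in enumerate(lfq)})
            recs.append(rec)
        cols = (["protein_id", "gene_symbol"]
                + [f"sc_rep{i+1}" for i in range(n)]
                + [f"lfq_rep{i+1}" for i in range(n)])
        return pd.DataFrame(recs, columns=cols)

    bait_table = QuantTable(name="bait", df=_frame(bait_rows))
    ctrl_table = QuantTable(name="control", df=_frame(ctrl_rows))

    truth = GroundTruth(
        bait=config.bait_accession,
        true_interactors={a for a, _ in true_ids},
        background={a for a, _ in bg_ids},
        contaminants={a for a, _ in cont_ids},
        planted_chain=chain_accs,
        planted_intermediate_triads=[],  # intermediates allocated by simulate_interactome
        shared_pathway_target=shared_target,
        intermediates=set(),
        symbol_of=symbol_of,
    )
    truth._triad_targets = triad_targets  # type: ignore[attr-defined]
    return bait_table, ctrl_table, truth


def simulate_coip_candidates(config: SimulationConfig, truth: GroundTruth) -> CandidateSet:
    """Second-method (co-IP-like) detection list.

    Each true prey is detected with probability ``coip_sensitivity``, except
    the planted skeleton which is always detected; background proteins slip
    in with probability ``coip_background_prob`` as method-specific false
    positives.
    """
    rng = np.random.default_rng([config.seed, 1])
    skeleton = truth.skeleton | {t for t in getattr(truth, "_triad_targets", [])}
    members = []
    for acc in sorted(truth.true_interactors):
        if acc in skeleton or rng.random() < config.coip_sensitivity:
            members.append(acc)
    for acc in sorted(truth.background):
        if rng.random() < config.coip_background_prob:
            members.append(acc)
    df = pd.DataFrame({
        "protein_id": members,
        "gene_symbol": [truth.symbol_of[a] for a in members],
        "admission_reason": "detected",
    })
    return CandidateSet(method_label="coIP", df=df)


def simulate_mito_references(config: SimulationConfig, truth: GroundTruth):
    """Three overlapping mitochondrial reference lists.

    A ``mito_fraction_true`` share of true preys (skeleton first) is placed
    on at least one list; a ``mito_fraction_other`` share of background and
    contaminant proteins is too (real contaminant preys are often genuinely
    mitochondrial).  Two lists are accession-keyed, one gene-symbol-keyed.
    Returns a list of (name, id_space, members) triples.
    """
    rng = np.random.default_rng([config.seed, 2])
    true_sorted = sorted(truth.true_interactors)
    skeleton = truth.skeleton
    ordered = sorted(skeleton) + [a for a in true_sorted if a not in skeleton]
    n_mito = int(round(config.mito_fraction_true * len(ordered)))
    mito_true = ordered[:n_mito]
    others = sorted(truth.background | truth.contaminants)
    mito_other = [a for a in others if rng.random() < config.mito_fraction_other]
    pool = mito_true + mito_other

    lists = []
    for name, id_space, frac in (
        ("MitoCarta-like", "accession", 0.8),
        ("IMPI-like", "accession", 0.7),
        ("GO-mito-like", "gene_symbol", 0.6),
    ):
        members = {a for a in pool if rng.random() < frac}
        lists.append((name, id_space, members))
    # union must cover the pool exactly: assign stragglers to the first list
    covered = set().union(*(m for _, _, m in lists)) if lists else set()
    lists[0][2].update(set(pool) - covered)
    if any(id_space == "gene_symbol" for _, id_space, _ in lists):
        lists = [
            (name, id_space,
             {truth.symbol_of[a] for a in members} if id_space == "gene_symbol" else members)
            for name, id_space, members in lists
        ]
    return lists


def _draw_type(rng: np.random.Generator, spec: GraphSpec) -> str:
    types = list(spec.edge_type_weights)
    w = np.array([spec.edge_type_weights[t] for t in types], dtype=float)
    return str(rng.choice(types, p=w / w.sum()))


def simulate_interactome(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Typed interactome edge table with the planted topology.

    Emits the bait-anchored chain and, for each triad, the bait-intermediate
    and intermediate-target edges with NO direct bait-target edge.  With
    ``extra_edges_per_node`` = 0 the edge count is exactly chain length +
    2 x n_triads.  Noise edges are proximity-biased (each eligible node
    attaches near the bait's first shell) and never touch the chain
    interior, the bait-triad-target pairs, or the triad targets, so planted
    distances and the landscape diameter are preserved.

    Updates ``truth.planted_intermediate_triads`` and ``truth.intermediates``
    with the freshly allocated database-only intermediate nodes.
    """
    rng = np.random.default_rng([config.seed, 3])
    gs = config.graph_spec
    bait = truth.bait
    chain = truth.planted_chain
    triad_targets = list(getattr(truth, "_triad_targets", []))

    inter_ids = _make_identifiers(rng, len(triad_targets))
    # regenerate on collision with existing universe
    existing = set(truth.symbol_of)
    while any(a in existing for a, _ in inter_ids):
        inter_ids = _make_identifiers(rng, len(triad_targets))
    triads = []
    for (i_acc, i_sym), t_acc in zip(inter_ids, triad_targets):
        truth.symbol_of[i_acc] = i_sym
        truth.intermediates.add(i_acc)
        triads.append((bait, i_acc, t_acc))
    truth.planted_intermediate_triads = triads

    edges: list[tuple[str, str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()

    def add(a: str, b: str, etype: str, source: str) -> None:
        if a == b:
            return
        key = (min(a, b), max(a, b), etype)
        if key in seen:
            return
        seen.add(key)
        edges.append((a, b, etype, source))

    for a, b in zip(chain, chain[1:]):
        add(a, b, "physical", "planted-chain")
    for b_, i, t in triads:
        add(b_, i, "physical", "planted-triad")
        add(i, t, "physical", "planted-triad")

    chain_interior = set(chain[2:])  # nodes at planted levels >= 2
    triad_target_set = set(triad_targets)
    forbidden_endpoints = chain_interior | triad_target_set

    universe = sorted((truth.true_interactors | truth.background | truth.contaminants)
                      - set(chain[1:]) - triad_target_set)
    # attach free members only via detected L1 nodes (never via the
    # database-only intermediates), so the planted triads are the only
    # intermediate-dropout cases
    first_shell = sorted({chain[1]} if len(chain) > 1 else set())
    attached_members: list[str] = []

    for node in universe:
        is_member = node in truth.true_interactors
        for j in range(gs.extra_edges_per_node):
            if is_member and j == 0:
                # anchor each free member near the bait: direct edge or via L1
                if rng.random() < 0.5:
                    add(bait, node, _draw_type(rng, gs), "noise")
                    attached_members.append(node)
                else:
                    pool = first_shell + attached_members
                    partner = pool[rng.integers(len(pool))] if pool else bait
                    add(node, partner, _draw_type(rng, gs), "noise")
            else:
                partner = universe[rng.integers(len(universe))]
                if partner == node or partner in forbidden_endpoints or partner == bait:
                    continue
                add(node, partner, _draw_type(rng, gs), "noise")

    return pd.DataFrame(edges, columns=["id_a", "id_b", "type", "source"])


def simulate_pathways(
    truth: GroundTruth, n_biosystems: int = 20, seed: int = 0
):
    """Biosystem gene sets (GMT-ready) with a planted shared-pathway target.

    The bait belongs to three tagged biosystems; the shared-pathway target
    shares the first two of them with the bait; every other prey is allowed
    in at most one bait biosystem, so the planted target uniquely maximizes
    the shared-biosystem score.  Remaining biosystems get random members.

    Returns (biosystems, tags): an ordered list of (name, description,
    member set) and a {name: relevance-tag} map; memberships are also
    recorded in ``truth.biosystem_membership``.
    """
    if n_biosystems < 1:
        raise ConfigurationError("n_biosystems must be >= 1")
    rng = np.random.default_rng([seed, 4])
    universe = sorted(truth.true_interactors | truth.background | truth.contaminants)
    bait = truth.bait
    shared = truth.shared_pathway_target

    names = [f"biosystem_{i+1:02d}" for i in range(n_biosystems)]
    tags = {}
    tag_cycle = ("FXN-function", "mitochondrial-biology", "FRDA-pathogenesis")
    biosystems: list[tuple[str, str, set]] = []

    n_bait_sets = min(3, n_biosystems)
    non_shared = [a for a in universe if a != shared]
    rng.shuffle(non_shared)
    # disjoint slices: each non-shared protein sits in at most one bait biosystem
    slice_size = max(3, len(non_shared) // max(6, 2 * n_bait_sets))
    for i in range(n_bait_sets):
        members = {bait}
        if shared is not None and i < 2:
            members.add(shared)
        members.update(non_shared[i * slice_size: (i + 1) * slice_size])
        tags[names[i]] = tag_cycle[i % 3]
        biosystems.append((names[i], f"planted bait biosystem {i+1}", members))

    for i in range(n_bait_sets, n_biosystems):
        k = int(rng.integers(5, max(6, len(universe) // 8)))
        members = set(rng.choice(universe, size=min(k, len(universe)), replace=False))
        members.discard(bait)
        biosystems.append((names[i], "random biosystem", members))

    truth.biosystem_membership = {name: set(m) for name, _, m in biosystems}
    return biosystems, tags
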