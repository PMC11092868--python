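"""End-to-end pipeline: simulate/load -> call -> curate -> intersect ->
landscape -> integrate, with every intermediate artifact written to a run
directory and all counts collected in a deterministic JSON summary.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import pandas as pd

from . import __version__
from .quant import QuantTable, FilterConfig, CandidateSet, call_candidates
from .curation import ReferenceList, annotate_localization, mito_fraction, filter_mito
from .collection import intersect_methods, collection_report
from .landscape import (
    build_graph, assign_levels, landscape_diameter,
    classify_novelty, flag_intermediate_dropout,
)
from .pathways import (
    PathwayAnnotation, membership_matrix, biosystem_distance,
    build_cord_table, prioritize_targets,
)
from . import io as pio
from . import simulate as sim

__all__ = ["PipelineError", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {"enabled": True, "n_biosystems": 20},
    "filter": {},
    "use_probabilistic": False,
    "landscape": {"on_unreachable": "inf"},
    "prioritize_weights": {},
}


def load_config(path) -> dict:
    """Load a JSON or YAML pipeline configuration and merge with defaults."""
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    simulate_on = cfg.get("simulate", {}).get("enabled", False)
    if not simulate_on:
        inputs = cfg.get("inputs", {})
        required = ["bait_table", "control_table", "coip_table", "edges", "gmt", "bait"]
        missing = [k for k in required if k not in inputs]
        if missing:
            raise ValueError(
                f"config without simulation must provide inputs: missing {missing}"
            )
    FilterConfig(**cfg.get("filter", {}))  # raises on bad thresholds


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return [_jsonable(v) for v in sorted(obj, key=str)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the full workflow and return the summary dict.

    Writes every intermediate artifact under ``outdir`` plus
    ``summary.json`` (deterministic for a fixed config and seed) and
    ``run.log``.  A failure in any stage raises :class:`PipelineError`
    naming the stage; artifacts written so far are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("proxland")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    seed = int(config.get("seed", 0))
    summary: dict = {"seed": seed, "version": __version__}
    stage = "setup"
    try:
        # ---- inputs -------------------------------------------------------
        stage = "simulate" if config["simulate"].get("enabled", False) else "load"
        if stage == "simulate":
            sim_kwargs = {k: v for k, v in config["simulate"].items()
                          if k not in ("enabled", "n_biosystems")}
            sim_kwargs["seed"] = seed
            scfg = sim.SimulationConfig(**sim_kwargs)
            bait_t, ctrl_t, truth = sim.simulate_quant_tables(scfg)
            coip = sim.simulate_coip_candidates(scfg, truth)
            ref_specs = sim.simulate_mito_references(scfg, truth)
            refs = [ReferenceList(name=n, members=set(m), id_space=s)
                    for n, s, m in ref_specs]
            edges = sim.simulate_interactome(scfg, truth)
            biosystems, tags = sim.simulate_pathways(
                truth, n_biosystems=int(config["simulate"].get("n_biosystems", 20)),
                seed=seed)
            ann = PathwayAnnotation(biosystems=biosystems, tags=tags)
            bait_id = scfg.bait_accession
            aliases = dict(truth.symbol_of)
            bait_t.to_tsv(outdir / "bait_quant.tsv")
            ctrl_t.to_tsv(outdir / "control_quant.tsv")
            coip.to_tsv(outdir / "coip_candidates.tsv")
            pio.write_edge_tsv(edges, outdir / "edges.tsv")
            pio.write_mitab(edges, outdir / "edges.mitab")
            pio.write_gmt(biosystems, outdir / "biosystems.gmt")
            pio.write_tag_file(tags, outdir / "biosystem_tags.tsv")
            for ref in refs:
                ref.to_txt(outdir / f"ref_{ref.name}.txt")
            truth.to_json(outdir / "ground_truth.json")
        else:
            inputs = config["inputs"]
            bait_t = QuantTable.read_tsv(inputs["bait_table"], name="bait")
            ctrl_t = QuantTable.read_tsv(inputs["control_table"], name="control")
            coip = CandidateSet.read_tsv(inputs["coip_table"], method_label="coIP")
            refs = [ReferenceList.read_txt(r["path"], name=r.get("name"),
                                           id_space=r.get("id_space", "accession"))
                    for r in inputs.get("refs", [])]
            epath = str(inputs["edges"])
            edges = (pio.read_mitab(epath) if epath.endswith((".mitab", ".txt"))
                     else pio.read_edge_tsv(epath))
            tags = pio.read_tag_file(inputs["tags"]) if inputs.get("tags") else {}
            ann = pio.read_gmt(inputs["gmt"], tags=tags)
            bait_id = str(inputs["bait"])
            aliases = {}
            truth = None

        # ---- candidate calling -------------------------------------------
        stage = "call-candidates"
        fcfg = FilterConfig(**config.get("filter", {}))
        bioid = call_candidates(bait_t, ctrl_t, fcfg,
                                use_probabilistic=bool(config.get("use_probabilistic", False)))
        bioid.method_label = "BioID"
        bioid.to_tsv(outdir / "bioid_candidates.tsv")
        summary["bioid_report"] = bioid.report

        # ---- curation -----------------------------------------------------
        stage = "curate"
        if refs:
            bioid_ann = annotate_localization(bioid, refs)
            coip_ann = annotate_localization(coip, refs)
            summary["mito_percent"] = {
                "BioID": round(mito_fraction(bioid_ann), 2) if len(bioid_ann) else None,
                "coIP": round(mito_fraction(coip_ann), 2) if len(coip_ann) else None,
            }
            bioid_m = filter_mito(bioid_ann)
            coip_m = filter_mito(coip_ann)
            summary["counts_pre_mito"] = {"BioID": len(bioid), "coIP": len(coip)}
            summary["counts_post_mito"] = {"BioID": len(bioid_m), "coIP": len(coip_m)}
            bioid_m.to_tsv(outdir / "bioid_mito.tsv")
            coip_m.to_tsv(outdir / "coip_mito.tsv")
        else:
            bioid_m, coip_m = bioid, coip
            summary["mito_percent"] = None
            summary["counts_pre_mito"] = {"BioID": len(bioid), "coIP": len(coip)}
            summary["counts_post_mito"] = summary["counts_pre_mito"]

        # ---- intersection -------------------------------------------------
        stage = "intersect"
        both = intersect_methods(bioid_m, coip_m)
        both.to_tsv(outdir / "collection.tsv")
        summary["collection"] = collection_report(both, bioid_m, coip_m)

        # ---- landscape ----------------------------------------------------
        stage = "landscape"
        n_raw = len(edges)
        g_db = build_graph(edges, bait=bait_id, aliases=aliases)
        summary["edges"] = {"raw": n_raw, "deduplicated": g_db.n_edges,
                            "nodes": len(g_db.nodes)}
        levels = assign_levels(g_db)
        member_nodes = {g_db.resolve(p) or g_db.resolve(s)
                        for p, s in zip(both.df["protein_id"], both.df["gene_symbol"])}
        member_nodes.discard(None)
        member_nodes.discard(bait_id)
        if member_nodes:
            diam = landscape_diameter(
                levels, member_nodes,
                on_unreachable=config.get("landscape", {}).get("on_unreachable", "inf"))
            summary["diameter"] = {
                "value": diam.diameter if diam.diameter != math.inf else "inf",
                "target": diam.target,
                "witness_path": diam.witness_path,
            }
        else:
            summary["diameter"] = None
        novelty, tallies = classify_novelty(g_db, both)
        novelty.to_csv(outdir / "novelty.tsv", sep="\t", index=False)
        summary["novelty"] = tallies
        detected = (bioid_m.protein_ids | bioid_m.gene_symbols
                    | coip_m.protein_ids | coip_m.gene_symbols)
        flags = flag_intermediate_dropout(g_db, both, detected, novelty)
        summary["intermediate_dropout_flags"] = flags
        pio.write_cytoscape(
            levels.df,
            pd.DataFrame(
                [(a, b, k, ";".join(sorted(d["sources"])))
                 for a, b, k, d in g_db.g.edges(keys=True, data=True)],
                columns=["id_a", "id_b", "type", "source"]),
            outdir / "cytoscape",
        )

        # ---- pathway integration -----------------------------------------
        stage = "integrate"
        if ann.biosystems:
            matrix = membership_matrix(both, ann, bait=bait_id)
            matrix.to_csv(outdir / "membership_matrix.tsv", sep="\t")
            biodist = biosystem_distance(g_db, ann, collection=both)
            biodist.to_csv(outdir / "biosystem_distance.tsv", sep="\t", index=False)
            cord, unannotated = build_cord_table(both, levels, novelty, ann, graph=g_db)
            cord.to_csv(outdir / "cord_table.tsv", sep="\t", index=False)
            ranked = prioritize_targets(matrix, bait=bait_id, tags=ann.tags,
                                        weights=config.get("prioritize_weights") or {})
            ranked.to_csv(outdir / "prioritized_targets.tsv", sep="\t", index=False)
            summary["cord_rows"] = len(cord)
            summary["unannotated_members"] = unannotated
            summary["top_targets"] = ranked.head(5)[["protein_id", "score"]].to_dict("records")
        else:
            summary["cord_rows"] = 0
            summary["unannotated_members"] = []
            summary["top_targets"] = []

        if truth is not None:
            stage = "evaluate"
            called = bioid.protein_ids
            tp = len(called & truth.true_interactors)
            summary["evaluation"] = {
                "sensitivity": tp / len(truth.true_interactors) if truth.true_interactors else None,
                "precision": tp / len(called) if called else None,
            }

        stage = "summary"
        with open(outdir / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
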