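import pandas as pd
import pytest

import proxland as px
from proxland.quant import CandidateSet


@pytest.fixture(scope="session")
def sim_bundle():
    """One fully simulated study (seed 1): tables, truth, lists, graph inputs."""
    cfg = px.SimulationConfig(seed=1)
    bait, control, truth = px.simulate_quant_tables(cfg)
    coip = px.simulate_coip_candidates(cfg, truth)
    refs = px.simulate_mito_references(cfg, truth)
    edges = px.simulate_interactome(cfg, truth)
    biosystems, tags = px.simulate_pathways(truth, n_biosystems=20, seed=1)
    return {
        "config": cfg, "bait": bait, "control": control, "truth": truth,
        "coip": coip, "refs": refs, "edges": edges,
        "biosystems": biosystems, "tags": tags,
    }


@pytest.fixture()
def truth_collection(sim_bundle):
    """The planted true-interactor set packaged as an interaction collection."""
    truth = sim_bundle["truth"]
    df = pd.DataFrame({"protein_id": sorted(truth.true_interactors)})
    df["gene_symbol"] = [truth.symbol_of[a] for a in df["protein_id"]]
    df["admission_reason"] = "detected"
    return CandidateSet(method_label="both", df=df)


def make_quant_table(name, rows, n_replicates=3):
    """rows: list of (protein_id, gene_symbol, counts tuple, lfq tuple)."""
    recs = []
    for pid, sym, counts, lfq in rows:
        rec = {"protein_id": pid, "gene_symbol": sym}
        rec.update({f"sc_rep{i+1}": counts[i] for i in range(n_replicates)})
        rec.update({f"lfq_rep{i+1}": lfq[i] for i in range(n_replicates)})
        recs.append(rec)
    cols = (["protein_id", "gene_symbol"]
            + [f"sc_rep{i+1}" for i in range(n_replicates)]
            + [f"lfq_rep{i+1}" for i in range(n_replicates)])
    return px.QuantTable(name=name, df=pd.DataFrame(recs, columns=cols))


def make_candidates(ids, label="test"):
    df = pd.DataFrame({
        "protein_id": list(ids),
        "gene_symbol": [f"SYM_{i}" for i in ids],
        "admission_reason": "detected",
    })
    return CandidateSet(method_label=label, df=df)
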