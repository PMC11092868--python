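"""Cross-validated interaction collection: intersection of two methods.

Proteins called by both orthogonal detection methods (e.g. proximity
labeling and co-IP) form the interaction collection on which the landscape
is built.  Matching is keyed on accession with a logged gene-symbol
fallback, mirroring the curation module's rule.
"""

from __future__ import annotations

import logging

import pandas as pd

from .quant import CandidateSet

__all__ = ["intersect_methods", "collection_report"]

logger = logging.getLogger(__name__)


class InconsistentInputError(ValueError):
    pass


def intersect_methods(a: CandidateSet, b: CandidateSet) -> CandidateSet:
    """Members present in both sets, with provenance of both source labels.

    Primary key is the accession; a member of ``a`` missing from ``b`` by
    accession still matches if its gene symbol (case-insensitive) appears in
    ``b``, and the fallback is logged.
    """
    b_accs = b.protein_ids
    b_syms = {str(s).casefold() for s in b.gene_symbols}
    rows = []
    for _, row in a.df.iterrows():
        if row["protein_id"] in b_accs:
            rows.append(row)
        elif str(row["gene_symbol"]).casefold() in b_syms:
            logger.info(
                "intersection fallback: %s matched %s by gene symbol",
                row["protein_id"], row["gene_symbol"],
            )
            rows.append(row)
    df = (pd.DataFrame(rows).reset_index(drop=True) if rows
          else a.df.iloc[0:0].copy())
    df = df[["protein_id", "gene_symbol", "admission_reason"]
            + [c for c in df.columns if c not in
               ("protein_id", "gene_symbol", "admission_reason")]]
    df["source_methods"] = f"{a.method_label};{b.method_label}"
    report = {
        "n_a": len(a), "n_b": len(b), "n_both": len(df),
        "label_a": a.method_label, "label_b": b.method_label,
    }
    return CandidateSet(method_label="both", df=df, report=report)


def collection_report(
    c: CandidateSet, a: CandidateSet, b: CandidateSet
) -> dict:
    """Machine-readable summary: the three counts, Jaccard index, members."""
    if not (c.protein_ids <= a.protein_ids and
            all(pid in b.protein_ids
                or str(sym).casefold() in {str(s).casefold() for s in b.gene_symbols}
                for pid, sym in zip(c.df["protein_id"], c.df["gene_symbol"]))):
        raise InconsistentInputError("collection is not a subset of both inputs")
    union = len(a.protein_ids | b.protein_ids)
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_both": len(c),
        "jaccard": (len(c) / union) if union else 0.0,
        "members": sorted(c.protein_ids),
    }
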