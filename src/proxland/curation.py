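"""Mitochondrial curation of candidate sets.

Candidates are annotated against one or more mitochondrial localization
reference lists (MitoCarta-like, IMPI-like, GO-mitochondrion-like); a
candidate is flagged mitochondrial when it appears on at least one list
(union rule).  Accession matching is case-sensitive, gene-symbol matching
case-insensitive; when a candidate's identifier in a list's own id space
misses, the other identifier is tried and the fallback is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .quant import CandidateSet

__all__ = ["ReferenceList", "annotate_localization", "mito_fraction", "filter_mito"]

logger = logging.getLogger(__name__)

ID_SPACES = ("accession", "gene_symbol")


class UndefinedFractionError(ValueError):
    pass


@dataclass
class ReferenceList:
    """A named localization reference list in one identifier space."""

    name: str
    members: set
    id_space: str = "accession"

    def __post_init__(self) -> None:
        if self.id_space not in ID_SPACES:
            raise ValueError(f"id_space must be one of {ID_SPACES}")
        if not self.members:
            raise ValueError(f"reference list {self.name!r} is empty")
        if self.id_space == "gene_symbol":
            self.members = {str(m).casefold() for m in self.members}
        else:
            self.members = {str(m) for m in self.members}

    def contains(self, accession: str, gene_symbol: str) -> tuple[bool, bool]:
        """(hit, used_fallback) for a candidate with both identifiers."""
        if self.id_space == "accession":
            if accession in self.members:
                return True, False
            if str(gene_symbol).casefold() in {m.casefold() for m in self.members}:
                return True, True
            return False, False
        if str(gene_symbol).casefold() in self.members:
            return True, False
        if str(accession).casefold() in self.members:
            return True, True
        return False, False

    @classmethod
    def read_txt(cls, path, name: str | None = None, id_space: str = "accession") -> "ReferenceList":
        """Plain text, one identifier per line, ``#`` comments allowed."""
        members = set()
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    members.add(line)
        return cls(name=name or str(path), members=members, id_space=id_space)

    def to_txt(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.name} ({self.id_space})\n")
            for m in sorted(self.members):
                fh.write(m + "\n")


def annotate_localization(
    cands: CandidateSet, refs: list[ReferenceList]
) -> CandidateSet:
    """Flag each candidate as mitochondrial by membership in ANY reference list."""
    if not refs:
        raise ValueError("at least one reference list is required")
    flags, sources = [], []
    for _, row in cands.df.iterrows():
        hits = []
        for ref in refs:
            hit, fallback = ref.contains(row["protein_id"], row["gene_symbol"])
            if hit:
                hits.append(ref.name)
                if fallback:
                    logger.info(
                        "identifier fallback: %s/%s matched %s via the other id space",
                        row["protein_id"], row["gene_symbol"], ref.name,
                    )
        flags.append(bool(hits))
        sources.append(hits)
    df = cands.df.copy()
    df["mito"] = flags
    df["mito_sources"] = sources
    return CandidateSet(method_label=cands.method_label, df=df, report=dict(cands.report))


def mito_fraction(cands: CandidateSet) -> float:
    """Percentage of candidates flagged mitochondrial (exact value; round for display)."""
    if len(cands) == 0:
        raise UndefinedFractionError("mito fraction undefined on an empty candidate set")
    if "mito" not in cands.df.columns:
        raise ValueError("candidate set is not annotated; run annotate_localization first")
    return 100.0 * float(cands.df["mito"].sum()) / len(cands)


def filter_mito(cands: CandidateSet) -> CandidateSet:
    """Retain mitochondrially annotated members only."""
    if "mito" not in cands.df.columns:
        raise ValueError("candidate set is not annotated; run annotate_localization first")
    keep = cands.df["mito"].astype(bool)
    removed = cands.df.loc[~keep, ["protein_id", "gene_symbol"]]
    report = dict(cands.report)
    report["removed_non_mito"] = removed["protein_id"].tolist()
    return CandidateSet(
        method_label=cands.method_label,
        df=cands.df.loc[keep].reset_index(drop=True),
        report=report,
    )
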