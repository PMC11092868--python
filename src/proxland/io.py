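"""Readers and writers for the interchange formats.

* PSI-MI TAB 2.5 (15 tab-separated columns, ``uniprotkb:ACC`` identifiers,
  interaction type in column 12 as ``psi-mi:"MI:xxxx"(label)``) and a simple
  3-column TSV edge dialect ``id_a  id_b  type``;
* GMT gene sets (set name, description, tab-separated members) with an
  optional biosystem-tag TSV;
* node/edge TSV export suitable for Cytoscape import.

All writers produce byte-stable output for a fixed input; readers report
malformed lines with their line numbers and treat empty files as empty
structures with a warning.
"""

from __future__ import annotations

import logging
import re

import pandas as pd

from .pathways import PathwayAnnotation

__all__ = [
    "MI_TERMS",
    "read_mitab",
    "write_mitab",
    "read_edge_tsv",
    "write_edge_tsv",
    "read_gmt",
    "write_gmt",
    "read_tag_file",
    "write_tag_file",
    "write_cytoscape",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# internal mapping between edge types and PSI-MI controlled-vocabulary-style
# terms; types without a canonical MI interaction-type term get project-local
# codes in the MI:9xxx range so round-trips stay lossless.
MI_TERMS = {
    "physical": ("MI:0915", "physical association"),
    "co-localization": ("MI:0403", "colocalization"),
    "genetic": ("MI:0208", "genetic interaction"),
    "co-expression": ("MI:9901", "co-expression"),
    "shared-domain": ("MI:9902", "shared domain"),
    "pathway": ("MI:9903", "pathway association"),
}
_TYPE_BY_MI = {mi: t for t, (mi, _) in MI_TERMS.items()}
_TYPE_BY_LABEL = {label: t for t, (_, label) in MI_TERMS.items()}

_MI_RE = re.compile(r'psi-mi:"(MI:\d+)"\(([^)]*)\)')


def write_mitab(edges: pd.DataFrame, path) -> None:
    """Write an edge table as MITAB 2.5 (identifiers as ``uniprotkb:ACC``)."""
    with open(path, "w") as fh:
        for i, row in edges.iterrows():
            etype = str(row["type"])
            mi, label = MI_TERMS.get(etype, MI_TERMS["physical"])
            source = str(row["source"]) if "source" in edges.columns else "synthetic"
            cols = ["-"] * 15
            cols[0] = f"uniprotkb:{row['id_a']}"
            cols[1] = f"uniprotkb:{row['id_b']}"
            cols[11] = f'psi-mi:"{mi}"({label})'
            cols[12] = f"psi-mi:\"MI:0000\"({source})"
            cols[13] = f"synthetic:{i}"
            fh.write("\t".join(cols) + "\n")


def read_mitab(path) -> pd.DataFrame:
    """Parse MITAB 2.5 into an ``id_a, id_b, type, source`` edge table."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 15:
                raise ParseError(
                    f"{path}: line {lineno}: expected 15 tab-separated columns, got {len(cols)}"
                )
            id_a = cols[0].split(":", 1)[-1]
            id_b = cols[1].split(":", 1)[-1]
            m = _MI_RE.search(cols[11])
            if m:
                mi, label = m.group(1), m.group(2)
                etype = _TYPE_BY_MI.get(mi) or _TYPE_BY_LABEL.get(label)
                if etype is None:
                    logger.warning(
                        "%s: line %d: unknown interaction type %s(%s); mapped to 'physical'",
                        path, lineno, mi, label,
                    )
                    etype = "physical"
            elif cols[11] == "-":
                etype = "physical"
            else:
                raise ParseError(
                    f"{path}: line {lineno}: unparseable interaction type {cols[11]!r}"
                )
            sm = _MI_RE.search(cols[12])
            source = sm.group(2) if sm else "mitab"
            rows.append((id_a, id_b, etype, source))
    if not rows:
        logger.warning("%s: empty MITAB file", path)
    return pd.DataFrame(rows, columns=["id_a", "id_b", "type", "source"])


def write_edge_tsv(edges: pd.DataFrame, path) -> None:
    cols = ["id_a", "id_b", "type"] + (["source"] if "source" in edges.columns else [])
    edges[cols].to_csv(path, sep="\t", index=False)


def read_edge_tsv(path) -> pd.DataFrame:
    """Read the simple edge dialect; a header line is optional."""
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        logger.warning("%s: empty edge file", path)
        return pd.DataFrame(columns=["id_a", "id_b", "type"])
    has_header = first.split("\t")[0].strip() == "id_a"
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    if not has_header:
        names = ["id_a", "id_b", "type", "source"][: df.shape[1]]
        df.columns = names
    if df.shape[1] < 3:
        raise ParseError(f"{path}: edge TSV needs at least 3 columns (id_a, id_b, type)")
    return df


def write_gmt(biosystems: list, path) -> None:
    """One biosystem per line: name, description, tab-separated members (sorted)."""
    with open(path, "w") as fh:
        for name, description, members in biosystems:
            fh.write("\t".join([name, description] + sorted(members)) + "\n")


def read_gmt(path, tags: dict | None = None) -> PathwayAnnotation:
    biosystems = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT records need name, description and >= 1 member"
                )
            biosystems.append((cols[0], cols[1], set(cols[2:])))
    if not biosystems:
        logger.warning("%s: empty GMT file", path)
        return PathwayAnnotation(biosystems=[], tags={})
    return PathwayAnnotation(biosystems=biosystems, tags=tags or {})


def write_tag_file(tags: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("biosystem\ttag\n")
        for name in sorted(tags):
            fh.write(f"{name}\t{tags[name]}\n")


def read_tag_file(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["biosystem"], df["tag"]))


def write_cytoscape(nodes: pd.DataFrame, edges: pd.DataFrame, outdir) -> tuple[str, str]:
    """Node (id, level, class, call) and edge (a, b, type, source) TSVs."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    node_path = outdir / "nodes.tsv"
    edge_path = outdir / "edges.tsv"
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False)
    return str(node_path), str(edge_path)
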