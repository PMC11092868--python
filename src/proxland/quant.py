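"""Candidate-prey calling from bait vs control quantification tables.

A proximity-labeling (BioID) experiment yields, per protein, spectral counts
and label-free quantification (LFQ) intensities in each replicate, for a
bait-ligase line and a matched mitochondrially-targeted ligase-only (MTS)
control line.  A protein is called a high-affinity candidate for the bait
when it is reproducibly detected, and either absent from the control
pulldown or enriched at least ``control_fold_threshold``-fold over it.

The stages compose as::

    normalize_linear -> filter_min_counts -> filter_control_enrichment
                     -> (optional Poisson enrichment filter)

All tables are pandas DataFrames wrapped in :class:`QuantTable`; the final
call is a :class:`CandidateSet` recording, for every admitted protein, which
rule admitted it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QuantTable",
    "FilterConfig",
    "CandidateSet",
    "normalize_linear",
    "filter_min_counts",
    "filter_control_enrichment",
    "enrichment_probability",
    "call_candidates",
]

# "detected" marks members of an externally supplied detection list (e.g. a
# co-IP hit list) that did not pass through the bait/control filters here.
ADMISSION_REASONS = ("absent_from_control", "fold_change", "probabilistic", "detected")


class ConfigurationError(ValueError):
    """An invalid configuration value; the message names the field."""


class DegenerateInputError(ValueError):
    """An input that makes the operation undefined (e.g. an all-zero column)."""


def _sc_cols(n: int) -> list[str]:
    return [f"sc_rep{i}" for i in range(1, n + 1)]


def _lfq_cols(n: int) -> list[str]:
    return [f"lfq_rep{i}" for i in range(1, n + 1)]


@dataclass
class QuantTable:
    """Per-protein, per-replicate spectral counts and LFQ intensities.

    Parameters
    ----------
    name
        Label for the cell line ("bait", "control", ...).
    df
        DataFrame with columns ``protein_id``, ``gene_symbol``,
        ``sc_rep1..sc_repN`` (integer counts) and ``lfq_rep1..lfq_repN``
        (non-negative intensities).
    """

    name: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"protein_id", "gene_symbol"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"QuantTable {self.name!r} missing columns {sorted(missing)}")
        n = self.n_replicates
        if n == 0:
            raise ValueError(f"QuantTable {self.name!r} has no replicate columns")
        for c in self.sc_columns:
            vals = self.df[c]
            if (vals < 0).any():
                raise ValueError(f"negative spectral counts in column {c}")
            if not np.array_equal(vals.to_numpy(), vals.to_numpy().astype(int)):
                raise ValueError(f"non-integer spectral counts in column {c}")
        for c in self.lfq_columns:
            if (self.df[c] < 0).any():
                raise ValueError(f"negative LFQ values in column {c}")
        if self.df["protein_id"].duplicated().any():
            dup = self.df.loc[self.df["protein_id"].duplicated(), "protein_id"].iloc[0]
            raise ValueError(f"duplicate protein_id {dup!r} in table {self.name!r}")

    @property
    def n_replicates(self) -> int:
        return sum(c.startswith("sc_rep") for c in self.df.columns)

    @property
    def sc_columns(self) -> list[str]:
        return _sc_cols(self.n_replicates)

    @property
    def lfq_columns(self) -> list[str]:
        return _lfq_cols(self.n_replicates)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read_tsv(cls, path, name: str | None = None) -> "QuantTable":
        df = pd.read_csv(path, sep="\t")
        return cls(name=name or str(path), df=df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class FilterConfig:
    """Thresholds for candidate calling.

    ``min_replicates_detected`` implements the reproducibility filter
    (detected in at least that many replicates, detection meaning spectral
    count >= 1).  ``control_fold_threshold`` is the bait/control LFQ ratio
    above which a control-detected protein is still admitted.
    ``pseudocount`` stabilizes the ratio against zero LFQ means; if None it
    defaults to the smallest nonzero LFQ in the pair of tables.
    ``enrichment_alpha`` is used only by the optional Poisson filter.
    """

    min_replicates_detected: int = 2
    n_replicates: int = 3
    control_fold_threshold: float = 3.0
    pseudocount: float | None = None
    enrichment_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_replicates_detected < 0:
            raise ConfigurationError("min_replicates_detected must be >= 0")
        if self.min_replicates_detected > self.n_replicates:
            raise ConfigurationError(
                "min_replicates_detected must be <= n_replicates "
                f"({self.min_replicates_detected} > {self.n_replicates})"
            )
        if not self.control_fold_threshold > 0:
            raise ConfigurationError("control_fold_threshold must be > 0")
        if self.pseudocount is not None and self.pseudocount < 0:
            raise ConfigurationError("pseudocount must be >= 0")
        if not 0 <= self.enrichment_alpha <= 1:
            raise ConfigurationError("enrichment_alpha must be in [0, 1]")


@dataclass
class CandidateSet:
    """A named set of proteins surviving the filters, with provenance.

    ``df`` has one row per member with at least ``protein_id``,
    ``gene_symbol`` and ``admission_reason`` (one of
    ``absent_from_control``, ``fold_change``, ``probabilistic``); candidate
    calling adds ``mean_lfq_bait``, ``mean_lfq_control``, ``fold_change``
    and ``enrichment_p`` columns, curation adds ``mito``/``mito_sources``.
    """

    method_label: str
    df: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("protein_id", "gene_symbol", "admission_reason"):
            if col not in self.df.columns:
                raise ValueError(f"CandidateSet missing column {col!r}")
        if self.df["protein_id"].duplicated().any():
            raise ValueError("CandidateSet members must be unique by protein_id")
        bad = set(self.df["admission_reason"]) - set(ADMISSION_REASONS)
        if bad:
            raise ValueError(f"unknown admission_reason values {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def protein_ids(self) -> set[str]:
        return set(self.df["protein_id"])

    @property
    def gene_symbols(self) -> set[str]:
        return set(self.df["gene_symbol"])

    @classmethod
    def read_tsv(cls, path, method_label: str | None = None) -> "CandidateSet":
        df = pd.read_csv(path, sep="\t")
        return cls(method_label=method_label or str(path), df=df)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        for c in out.columns:
            if out[c].map(lambda v: isinstance(v, (list, tuple, set))).any():
                out[c] = out[c].map(lambda v: ";".join(sorted(map(str, v))) if isinstance(v, (list, tuple, set)) else v)
        out.to_csv(path, sep="\t", index=False)


def normalize_linear(bait: QuantTable, control: QuantTable) -> tuple[QuantTable, QuantTable]:
    """Rescale each replicate's LFQ column to a common total intensity.

    Every one of the ``2 x n_replicates`` LFQ columns is multiplied by a
    single factor so that all column totals equal the median of the original
    totals.  Spectral counts are untouched and row order is preserved; the
    bait/control ratio of any protein is invariant up to the per-column
    factors, so the operation is a linear normalization in the usual sense.
    """
    if bait.n_replicates != control.n_replicates:
        raise ValueError(
            f"replicate count mismatch: {bait.n_replicates} vs {control.n_replicates}"
        )
    totals = {}
    for table in (bait, control):
        for c in table.lfq_columns:
            totals[(table.name, c)] = float(table.df[c].sum())
    for (name, c), tot in totals.items():
        if tot == 0:
            raise DegenerateInputError(
                f"LFQ column {c!r} of table {name!r} has total intensity 0"
            )
    target = float(np.median(list(totals.values())))
    out = []
    for table in (bait, control):
        df = table.df.copy()
        for c in table.lfq_columns:
            df[c] = df[c] * (target / totals[(table.name, c)])
        out.append(replace(table, df=df))
    return out[0], out[1]


def filter_min_counts(table: QuantTable, cfg: FilterConfig) -> QuantTable:
    """Drop proteins detected (spectral count >= 1) in too few replicates.

    Retains rows with at least ``cfg.min_replicates_detected`` replicates
    having a nonzero spectral count; the removed rows are recorded on the
    returned table as ``removed_low_counts`` (a DataFrame) for reporting.
    """
    counts = table.df[table.sc_columns].to_numpy()
    detected = (counts >= 1).sum(axis=1)
    keep = detected >= cfg.min_replicates_detected
    kept = replace(table, df=table.df.loc[keep].reset_index(drop=True))
    removed = table.df.loc[~keep, ["protein_id", "gene_symbol"]].copy()
    removed["reason"] = [
        f"detected in {d} < {cfg.min_replicates_detected} replicates"
        for d in detected[~keep]
    ]
    kept.removed_low_counts = removed.reset_index(drop=True)  # type: ignore[attr-defined]
    return kept


def _resolve_pseudocount(bait: QuantTable, control: QuantTable, cfg: FilterConfig) -> float:
    if cfg.pseudocount is not None:
        return cfg.pseudocount
    vals = np.concatenate(
        [bait.df[bait.lfq_columns].to_numpy().ravel(),
         control.df[control.lfq_columns].to_numpy().ravel()]
    )
    nonzero = vals[vals > 0]
    return float(nonzero.min()) if nonzero.size else 1.0


def filter_control_enrichment(
    bait: QuantTable, control: QuantTable, cfg: FilterConfig
) -> CandidateSet:
    """Admit bait proteins absent from the control or >= threshold-fold enriched.

    A bait protein is a candidate iff (a) its accession is absent from the
    control table (``absent_from_control``), or (b) its mean LFQ over the
    replicates in which it was detected (nonzero LFQ), pseudocount added to
    both means, is at least ``control_fold_threshold`` times the control
    mean (``fold_change``).  Everything else is rejected as a control
    contaminant.  Zero LFQ marks a missing observation in that replicate,
    so it is excluded from the mean rather than diluting it; a protein with
    all-zero LFQ gets mean 0.
    """
    if bait.n_replicates != control.n_replicates:
        raise ValueError(
            f"replicate count mismatch: {bait.n_replicates} vs {control.n_replicates}"
        )
    pc = _resolve_pseudocount(bait, control, cfg)

    def _detected_mean(values: np.ndarray) -> float:
        nz = values[values > 0]
        return float(nz.mean()) if nz.size else 0.0

    ctrl_lfq = control.df.set_index("protein_id")[control.lfq_columns]
    ctrl_mean = ctrl_lfq.apply(lambda r: _detected_mean(r.to_numpy()), axis=1)

    rows = []
    rejected = []
    for _, row in bait.df.iterrows():
        pid = row["protein_id"]
        mean_bait = _detected_mean(np.array([row[c] for c in bait.lfq_columns]))
        if pid not in ctrl_mean.index:
            rows.append((pid, row["gene_symbol"], "absent_from_control",
                         mean_bait, np.nan, np.inf))
            continue
        mean_ctrl = float(ctrl_mean.loc[pid])
        fold = (mean_bait + pc) / (mean_ctrl + pc)
        if fold >= cfg.control_fold_threshold:
            rows.append((pid, row["gene_symbol"], "fold_change",
                         mean_bait, mean_ctrl, fold))
        else:
            rejected.append((pid, row["gene_symbol"], mean_bait, mean_ctrl, fold))
    df = pd.DataFrame(
        rows,
        columns=["protein_id", "gene_symbol", "admission_reason",
                 "mean_lfq_bait", "mean_lfq_control", "fold_change"],
    )
    report = {
        "input_rows": len(bait),
        "rejected_control_enriched": len(rejected),
        "admitted": len(df),
        "pseudocount": pc,
    }
    return CandidateSet(method_label=bait.name, df=df, report=report)


def enrichment_probability(
    bait_counts, control_counts, cfg: FilterConfig | None = None
) -> float:
    """Upper-tail Poisson probability of the observed total bait counts.

    The null takes the total bait spectral counts as Poisson with mean
    ``n_bait_replicates * (mean control count + 0.5)`` and returns
    ``P(X >= observed total)``.  Smaller values indicate stronger
    enrichment over the control.  This is a transparent surrogate for a
    full spectral-count mixture model and is used only as an optional
    additional filter, always reported alongside the rule-based admission.
    """
    bait_counts = np.asarray(bait_counts, dtype=float)
    control_counts = np.asarray(control_counts, dtype=float)
    if bait_counts.size == 0 or control_counts.size == 0:
        raise ValueError("count vectors must be nonempty")
    if (bait_counts < 0).any() or (control_counts < 0).any():
        raise ValueError("spectral counts must be nonnegative")
    total = float(bait_counts.sum())
    mu = bait_counts.size * (float(control_counts.mean()) + 0.5)
    # P(Pois(mu) >= total) = sf(total - 1)
    return float(stats.poisson.sf(math.ceil(total) - 1, mu))


def call_candidates(
    bait: QuantTable,
    control: QuantTable,
    cfg: FilterConfig | None = None,
    use_probabilistic: bool = False,
) -> CandidateSet:
    """Full candidate-calling composition with a per-stage run report.

    normalize_linear -> filter_min_counts -> filter_control_enrichment, then
    optionally the Poisson enrichment filter (keep if p <= enrichment_alpha).
    The Poisson p-value is computed and reported for every candidate either
    way.

    The reproducibility count filter is applied to the bait table only: the
    control is a false-positive reference, so its low-count identifications
    are kept as evidence of control presence rather than being discarded
    (dropping them would promote shared background to absent-from-control
    candidates).
    """
    cfg = cfg or FilterConfig()
    n_input = len(bait)
    if n_input == 0:
        empty = pd.DataFrame(columns=["protein_id", "gene_symbol", "admission_reason"])
        return CandidateSet(
            method_label=bait.name, df=empty,
            report={"input_rows": 0, "removed_low_counts": 0,
                    "rejected_control_enriched": 0, "removed_probabilistic": 0,
                    "final": 0},
        )
    bait_n, control_n = normalize_linear(bait, control)
    bait_f = filter_min_counts(bait_n, cfg)
    cands = filter_control_enrichment(bait_f, control_n, cfg)

    sc = bait_f.df.set_index("protein_id")[bait_f.sc_columns]
    ctrl_sc = control_n.df.set_index("protein_id")[control_n.sc_columns]
    zeros = np.zeros(control_n.n_replicates)
    pvals = []
    for pid in cands.df["protein_id"]:
        ctrl = ctrl_sc.loc[pid].to_numpy() if pid in ctrl_sc.index else zeros
        pvals.append(enrichment_probability(sc.loc[pid].to_numpy(), ctrl, cfg))
    cands.df["enrichment_p"] = pvals

    removed_prob = 0
    if use_probabilistic:
        keep = cands.df["enrichment_p"] <= cfg.enrichment_alpha
        removed_prob = int((~keep).sum())
        cands = CandidateSet(
            method_label=cands.method_label,
            df=cands.df.loc[keep].reset_index(drop=True),
            report=cands.report,
        )
    cands.report = {
        "input_rows": n_input,
        "removed_low_counts": n_input - len(bait_f),
        "rejected_control_enriched": cands.report.get("rejected_control_enriched", 0),
        "removed_probabilistic": removed_prob,
        "final": len(cands),
    }
    return cands
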