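# Methods

## Candidate-prey calling

The quantitative unit is a per-protein, per-replicate pair of spectral
counts and LFQ intensities for a bait-ligase line and a matched
ligase-only control. Three filters compose, in order:

1. **Linear normalization.** Every LFQ replicate column (2 lines × n
   replicates) is multiplied by one factor so all column totals equal the
   median of the original totals. The median target makes the operation
   deterministic and robust to a single aberrant run; spectral counts are
   never rescaled. A column with total 0 is rejected as degenerate rather
   than silently scaled.
2. **Reproducibility.** A protein must be detected (count ≥ 1) in at
   least `min_replicates_detected` (default 2 of 3) replicates. The
   phrase "detected" counts replicates, not summed spectra: this is the
   standard reproducibility filter, and the boundary (exactly 2 of 3) is
   retained. The filter applies to the *bait* table only. The control is
   a false-positive reference: discarding its low-count identifications
   would promote genuinely shared background to "absent from control"
   candidates, so control evidence is kept in full.
3. **Control enrichment.** A bait protein absent from the control is a
   candidate (`absent_from_control`); otherwise it must satisfy
   (mean bait LFQ + ε) / (mean control LFQ + ε) ≥ 3 (`fold_change`,
   boundary inclusive). Means are taken over replicates with nonzero LFQ:
   a zero LFQ records a missing observation (the protein was not
   quantified in that run), and averaging it in would conflate detection
   dropout with abundance. A protein quantified in no replicate gets mean
   0. The pseudocount ε defaults to the smallest nonzero LFQ in the pair
   of tables, which stabilizes ratios for weakly quantified proteins at
   the cost of a conservative bias near the threshold.

An optional **Poisson enrichment surrogate** reports, per candidate, the
upper tail P(X ≥ total bait counts) for X ~ Poisson(n·(mean control count
+ 0.5)). It is a transparent spectral-count test — deliberately not a
full bait-prey mixture model — reported always, applied as a filter
(p ≤ 0.05) only on request, and off by default.

Identity across tables is the accession; gene symbols are carried for
reporting, graph queries and as a logged fallback key.

## Curation, intersection

A candidate is mitochondrial if it appears on **any** of the supplied
reference lists (union, per the "at least one database" rule). Accessions
match case-sensitively, gene symbols case-insensitively; a miss in a
list's own identifier space falls back to the candidate's other
identifier, and every fallback is logged. Because reported interactome
counts in this setting are ambiguous about whether they pre- or post-date
compartment filtering, the pipeline reports both counts. The interaction
collection is the accession-keyed intersection of the two method sets
(symbol fallback logged), with the three counts and the Jaccard index in
the run summary.

## Landscape

The interactome is an undirected multigraph keyed by edge type
({physical, co-expression, co-localization, shared-domain, pathway,
genetic}); duplicate (a, b, type) records merge their sources; unknown
types map to `physical` with a warning. BFS from the bait over all edge
types (type-restricted views available via a filter) yields levels;
**path length counts edges**, the convention fixed by the published
seven-protein chain with maximum path 6. Level 1 = direct, 2–3 =
indirect, ≥ 4 or unreachable = non-proximal — the only consistent
completion of the three-class scheme. Witness paths break ties by
lexicographic node order, so outputs are deterministic and row-order
invariant.

Novelty, against a database-only graph: a direct database edge to the
bait → `known_direct`; database distance 2–3 → `new_direct` (also tallied
as new-indirect for its database path, so the two tallies are not forced
to partition the collection); finite distance ≥ 4 → `new_direct` flagged
"no proximal database support"; absent/disconnected → `unconnected`.
Distance-2 members whose *every* shortest-path intermediate is missing
from the union of single-method candidate sets are flagged as
intermediate-dropout cases, proposing a direct bait contact and naming
the undetected intermediates.

## Pathway integration

Binary membership matrix over (collection ∪ bait) × biosystems; per-
biosystem distance = min member level, computed on the database graph and
again with one experimental bait–member edge per collection member (the
delta shows the connectivity gained); a cord-diagram backing table with
one row per (member, biosystem) pair carrying the first witness-path hop
type and the novelty call. Prioritization scores each member by the sum
of relevance-tag weights (default 1) over biosystems shared with the
bait; it is the minimal formalization of "shared pathways of relevance",
labeled as such — no enrichment p-value is computed because the workflow
performs selection, not enrichment testing.

## Synthetic benchmark

The generator emulates post-quantification BioID tables, not spectra.

* **Counts** ~ Poisson: rate 8/replicate for true preys, 1 for
  background; **LFQ** ~ log-normal with σ = 0.2 (log10) around a
  per-protein base intensity. True preys are enriched 5× in the bait
  line and suffer per-replicate dropout (p = 0.1, zeroing both count and
  LFQ). Defaults: 30 true preys, 170 background, 20 contaminants, 3
  replicates.
* **Abundance structure.** Background (log10 base 6.5 ± 0.3) dominates
  total intensity, as in real pulldowns where bait-specific signal is a
  small fraction — this keeps total-intensity normalization near-neutral
  between lines. True preys sit lower (5.5 ± 0.3); contaminants
  (6.5 ± 0.3) are control-enriched by a uniform 1–3× factor so the fold
  filter has true negatives. Only a minority of true preys
  (`true_control_presence` = 0.25) leak into the control at base
  intensity: absence from a ligase-only control is the premise of
  control subtraction, so most true preys are control-absent.
* **Second method.** Each true prey enters the co-IP-like list with
  probability 0.9; background slips in at 0.05. The planted *skeleton*
  (chain members, triad targets, shared-pathway target) is always
  detected, so landscape-level properties are deterministic functions of
  the topology while quantitative recovery stays stochastic.
* **Topology.** A 6-edge chain rooted at the bait fixes the landscape
  diameter; 3 bait–intermediate–target triads with database-only
  intermediates (never present in any quantification table) plant the
  intermediate-dropout cases, with no direct bait–target edge; every
  other member is anchored at distance ≤ 2 via the bait or a detected
  level-1 node; noise edges (2 per eligible node) never touch the chain
  interior or the triad targets, so planted distances are invariants, and
  never attach through undetected intermediates, so the triads are the
  only dropout cases. With zero noise edges the edge count is exactly
  chain + 2 × triads.
* **Pathways.** The bait sits in three tagged biosystems; the planted
  shared-pathway target shares the first two; every other protein is
  restricted to at most one bait biosystem, so the planted target
  uniquely maximizes the shared-biosystem score. Remaining biosystems are
  random draws.
* **References.** 95% of true preys (skeleton first) and 30% of other
  proteins land on at least one of three overlapping lists (two
  accession-keyed, one symbol-keyed), exercising both identifier spaces.

What the generator does **not** emulate: peptide-level identity and
shared-peptide inference, intensity-dependent missingness, batch and
carry-over effects, correlated contaminant structure (keratins etc.), or
realistic interactome degree distributions. Passing tests therefore
demonstrate correctness of the pipeline's logic and its statistical
behavior under the stated generative model, not performance on real MS
data.

Under these defaults, candidate calling recovers the planted preys at
roughly 0.92 mean sensitivity and 0.99 mean precision over 20 seeds (the
residual misses are preys whose 5× enrichment is pushed under the 3×
threshold by LFQ noise or pseudocount shrinkage, plus occasional double
dropout) — the test suite asserts the 0.90 ± 0.05 band.

## Numerical and design notes

* Determinism: all generators draw from `numpy.random.default_rng`
  seeded per sub-stream from the single configured seed; identical
  config + seed gives byte-identical artifacts, including the pipeline
  summary JSON.
* Degenerate inputs: empty tables yield empty candidate sets with
  explicit reports; empty files parse to empty structures with warnings;
  zero-total LFQ columns, unreachable diameter targets (configurable
  error-or-∞), and empty reference lists raise named errors.
* MITAB 2.5: edge types without a canonical PSI-MI interaction-type term
  use project-local codes in the MI:99xx range so round-trips are
  lossless; unknown incoming terms map to `physical` with a warning.
* Problem sizes in the test suite (graphs ≤ 8 nodes for the exhaustive
  BFS oracle, ≤ 20-row tables for the filter oracle, 10–20 seeds for
  recovery suites) are chosen so each oracle is exact and the full suite
  runs in seconds.

## Known limitations

* The Poisson surrogate ignores protein length and overdispersion; it is
  a reporting aid, not a calibrated FDR.
* Identifier reconciliation is a two-key (accession/symbol) fallback, not
  a full mapping service; ambiguous symbols shared by distinct accessions
  would be merged by the fallback and are only surfaced through the log.
* Biosystem distance uses the unweighted graph; no edge-type weighting is
  attempted because no principled weights exist in this setting.
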