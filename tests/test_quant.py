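"""Candidate-calling filters: worked examples, oracle equivalence, properties."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import proxland as px
from proxland.quant import (
    FilterConfig, ConfigurationError, DegenerateInputError,
    normalize_linear, filter_min_counts, filter_control_enrichment,
    enrichment_probability, call_candidates,
)
from .conftest import make_quant_table


class TestNormalizeLinear:
    def test_toy_median_target(self):
        """Three proteins, bait columns summing to 30 vs control to 60:
        the common total is the median (45), via factors 1.5 and 0.75."""
        bait = make_quant_table("bait", [
            ("P1", "A", (1, 1, 1), (10.0, 10.0, 10.0)),
            ("P2", "B", (1, 1, 1), (10.0, 10.0, 10.0)),
            ("P3", "C", (1, 1, 1), (10.0, 10.0, 10.0)),
        ])
        ctrl = make_quant_table("control", [
            ("P1", "A", (1, 1, 1), (20.0, 20.0, 20.0)),
            ("P2", "B", (1, 1, 1), (20.0, 20.0, 20.0)),
            ("P3", "C", (1, 1, 1), (20.0, 20.0, 20.0)),
        ])
        bn, cn = normalize_linear(bait, ctrl)
        for c in bn.lfq_columns:
            assert bn.df[c].sum() == pytest.approx(45.0)
            assert cn.df[c].sum() == pytest.approx(45.0)
        assert bn.df["lfq_rep1"].iloc[0] == pytest.approx(15.0)  # factor 1.5
        assert cn.df["lfq_rep1"].iloc[0] == pytest.approx(15.0)  # factor 0.75

    def test_ratios_preserved_for_identical_tables(self):
        rows = [("P1", "A", (2, 2, 2), (5.0, 7.0, 9.0)),
                ("P2", "B", (2, 2, 2), (1.0, 2.0, 3.0))]
        bait = make_quant_table("bait", rows)
        ctrl = make_quant_table("control", rows)
        bn, cn = normalize_linear(bait, ctrl)
        ratio = bn.df["lfq_rep1"] / cn.df["lfq_rep1"]
        assert np.allclose(ratio, 1.0)

    def test_doubled_column_rescaled_to_common_total(self):
        bait = make_quant_table("bait", [("P1", "A", (1, 1, 1), (20.0, 10.0, 10.0))])
        ctrl = make_quant_table("control", [("P1", "A", (1, 1, 1), (10.0, 10.0, 10.0))])
        bn, cn = normalize_linear(bait, ctrl)
        totals = [bn.df[c].sum() for c in bn.lfq_columns] + \
                 [cn.df[c].sum() for c in cn.lfq_columns]
        assert np.allclose(totals, totals[0])

    def test_zero_total_column_is_degenerate(self):
        bait = make_quant_table("bait", [("P1", "A", (1, 1, 1), (0.0, 10.0, 10.0))])
        ctrl = make_quant_table("control", [("P1", "A", (1, 1, 1), (10.0, 10.0, 10.0))])
        with pytest.raises(DegenerateInputError, match="lfq_rep1"):
            normalize_linear(bait, ctrl)

    def test_counts_untouched_and_order_preserved(self):
        bait = make_quant_table("bait", [
            ("P2", "B", (3, 0, 1), (10.0, 10.0, 10.0)),
            ("P1", "A", (1, 2, 3), (30.0, 10.0, 10.0)),
        ])
        ctrl = make_quant_table("control", [("P1", "A", (1, 1, 1), (10.0, 10.0, 10.0))])
        bn, _ = normalize_linear(bait, ctrl)
        assert list(bn.df["protein_id"]) == ["P2", "P1"]
        assert bn.df[bn.sc_columns].equals(bait.df[bait.sc_columns])


class TestFilterMinCounts:
    @pytest.mark.parametrize("counts,kept", [
        ((1, 0, 0), False),   # one replicate only
        ((1, 1, 0), True),    # boundary: 2 of 3
        ((0, 0, 0), False),
        ((5, 3, 2), True),
    ])
    def test_replicate_presence_rule(self, counts, kept):
        t = make_quant_table("bait", [("P1", "A", counts, (1.0, 1.0, 1.0))])
        out = filter_min_counts(t, FilterConfig())
        assert (len(out) == 1) is kept


class TestControlEnrichment:
    def test_absent_from_control_is_candidate(self):
        bait = make_quant_table("bait", [("P1", "A", (3, 3, 3), (100.0, 100.0, 100.0))])
        ctrl = make_quant_table("control", [("P9", "Z", (3, 3, 3), (100.0, 100.0, 100.0))])
        out = filter_control_enrichment(bait, ctrl, FilterConfig(pseudocount=0.0))
        assert list(out.df["admission_reason"]) == ["absent_from_control"]

    def test_threshold_boundary_inclusive(self):
        bait = make_quant_table("bait", [("P1", "A", (3, 3, 3), (300.0, 300.0, 300.0))])
        ctrl = make_quant_table("control", [("P1", "A", (3, 3, 3), (100.0, 100.0, 100.0))])
        out = filter_control_enrichment(bait, ctrl, FilterConfig(pseudocount=0.0))
        assert list(out.df["admission_reason"]) == ["fold_change"]

    def test_below_threshold_rejected(self):
        bait = make_quant_table("bait", [("P1", "A", (3, 3, 3), (150.0, 150.0, 150.0))])
        ctrl = make_quant_table("control", [("P1", "A", (3, 3, 3), (100.0, 100.0, 100.0))])
        out = filter_control_enrichment(bait, ctrl, FilterConfig(pseudocount=0.0))
        assert len(out) == 0

    def test_mismatched_replicates_rejected(self):
        bait = make_quant_table("bait", [("P1", "A", (3, 3), (1.0, 1.0))], n_replicates=2)
        ctrl = make_quant_table("control", [("P1", "A", (3, 3, 3), (1.0, 1.0, 1.0))])
        with pytest.raises(ValueError, match="replicate"):
            filter_control_enrichment(bait, ctrl, FilterConfig())


class TestEnrichmentProbability:
    def test_all_zero_counts_give_p_one(self):
        # null mean 3 * (0 + 0.5) = 1.5; P(Pois(1.5) >= 0) = 1
        assert enrichment_probability((0, 0, 0), (0, 0, 0)) == pytest.approx(1.0)

    def test_equal_counts_not_enriched(self):
        # total 15 against null mean 3 * 5.5 = 16.5
        p = enrichment_probability((5, 5, 5), (5, 5, 5))
        assert p > 0.05

    def test_matches_brute_force_tail_sum(self):
        # bait (10,9,11) vs control all-zero: P(Pois(1.5) >= 30)
        p = enrichment_probability((10, 9, 11), (0, 0, 0))
        mu, total = 1.5, 30
        # upper-tail summed directly (recurrence term_{k+1} = term_k * mu/(k+1))
        # to avoid both cancellation at ~1e-28 and factorial overflow
        term = math.exp(-mu)
        for k in range(1, total + 1):
            term *= mu / k
        brute, t = 0.0, term
        for k in range(total, 150):
            brute += t
            t *= mu / (k + 1)
        assert p == pytest.approx(brute, rel=1e-9)
        assert p < 1e-20

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_probability((-1, 0, 0), (0, 0, 0))


def _brute_force_calls(bait, ctrl, cfg):
    """Independent row-by-row re-evaluation of the two admission rules."""
    ctrl_rows = {r["protein_id"]: r for _, r in ctrl.df.iterrows()}
    nonzero = [v for t in (bait, ctrl) for c in t.lfq_columns
               for v in t.df[c] if v > 0]
    pc = cfg.pseudocount if cfg.pseudocount is not None else (min(nonzero) if nonzero else 1.0)
    admitted = {}
    for _, row in bait.df.iterrows():
        detected = sum(row[c] >= 1 for c in bait.sc_columns)
        if detected < cfg.min_replicates_detected:
            continue
        lfq = [row[c] for c in bait.lfq_columns if row[c] > 0]
        mb = sum(lfq) / len(lfq) if lfq else 0.0
        if row["protein_id"] not in ctrl_rows:
            admitted[row["protein_id"]] = "absent_from_control"
            continue
        crow = ctrl_rows[row["protein_id"]]
        clfq = [crow[c] for c in ctrl.lfq_columns if crow[c] > 0]
        mc = sum(clfq) / len(clfq) if clfq else 0.0
        if (mb + pc) / (mc + pc) >= cfg.control_fold_threshold:
            admitted[row["protein_id"]] = "fold_change"
    return admitted


class TestCallCandidates:
    def test_empty_bait_table(self):
        bait = make_quant_table("bait", [])
        ctrl = make_quant_table("control", [("P1", "A", (1, 1, 1), (1.0, 1.0, 1.0))])
        out = call_candidates(bait, ctrl)
        assert len(out) == 0
        assert out.report["input_rows"] == 0

    def test_huge_threshold_keeps_only_absent(self, sim_bundle):
        cfg = FilterConfig(control_fold_threshold=1e12)
        out = call_candidates(sim_bundle["bait"], sim_bundle["control"], cfg)
        assert set(out.df["admission_reason"]) <= {"absent_from_control"}

    def test_report_counts_are_consistent(self, sim_bundle):
        out = call_candidates(sim_bundle["bait"], sim_bundle["control"])
        r = out.report
        assert r["input_rows"] == len(sim_bundle["bait"])
        assert r["final"] == len(out)
        assert (r["input_rows"] - r["removed_low_counts"]
                - r["rejected_control_enriched"] == r["final"])

    def test_probabilistic_filter_is_subset(self, sim_bundle):
        loose = call_candidates(sim_bundle["bait"], sim_bundle["control"])
        strict = call_candidates(sim_bundle["bait"], sim_bundle["control"],
                                 use_probabilistic=True)
        assert strict.protein_ids <= loose.protein_ids
        assert (strict.df["enrichment_p"] <= 0.05).all()

    def test_brute_force_oracle_on_random_tables(self):
        """Filter decisions on random <=20-row tables match an independent
        re-evaluation of the replicate-presence and fold-change rules."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(1, 21))
            ids = [f"P{i}" for i in range(n)]
            def table(name):
                rows = []
                for pid in ids:
                    if name == "control" and rng.random() < 0.3:
                        continue
                    counts = tuple(int(c) for c in rng.poisson(2, 3))
                    lfq = tuple(float(v) for v in
                                np.where(rng.random(3) < 0.2, 0.0,
                                         rng.lognormal(3, 1, 3)))
                    rows.append((pid, pid.lower(), counts, lfq))
                return make_quant_table(name, rows)
            bait, ctrl = table("bait"), table("control")
            if len(bait) == 0 or any(bait.df[c].sum() == 0 for c in bait.lfq_columns) \
                    or len(ctrl) == 0 or any(ctrl.df[c].sum() == 0 for c in ctrl.lfq_columns):
                continue
            cfg = FilterConfig(pseudocount=0.5)
            got = call_candidates(bait, ctrl, cfg)
            # oracle works on unnormalized tables: normalize first the same way
            bn, cn = normalize_linear(bait, ctrl)
            expected = _brute_force_calls(bn, cn, cfg)
            assert dict(zip(got.df["protein_id"], got.df["admission_reason"])) == expected


class TestInvariants:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=1e4))
    def test_scale_invariance(self, scale):
        """Multiplying all LFQ of both tables by a constant leaves calls unchanged."""
        cfg = px.SimulationConfig(seed=5, n_true_interactors=10, n_background=30,
                                  n_contaminants=5)
        bait, ctrl, _ = px.simulate_quant_tables(cfg)
        base = call_candidates(bait, ctrl)
        for t in (bait, ctrl):
            for c in t.lfq_columns:
                t.df[c] = t.df[c] * scale
        scaled = call_candidates(bait, ctrl)
        assert scaled.protein_ids == base.protein_ids

    @pytest.mark.parametrize("field,values", [
        ("control_fold_threshold", [1.5, 3.0, 6.0, 12.0]),
        ("min_replicates_detected", [0, 1, 2, 3]),
    ])
    def test_threshold_monotonicity(self, sim_bundle, field, values):
        """Raising either threshold never increases the candidate set."""
        sizes = []
        for v in values:
            cfg = FilterConfig(**{field: v})
            sizes.append(len(call_candidates(sim_bundle["bait"], sim_bundle["control"], cfg)))
        assert sizes == sorted(sizes, reverse=True)


class TestFilterConfig:
    @pytest.mark.parametrize("kwargs,msg", [
        ({"min_replicates_detected": 4, "n_replicates": 3}, "min_replicates_detected"),
        ({"control_fold_threshold": 0}, "control_fold_threshold"),
        ({"enrichment_alpha": 1.5}, "enrichment_alpha"),
        ({"pseudocount": -1.0}, "pseudocount"),
    ])
    def test_invalid_values_name_the_field(self, kwargs, msg):
        with pytest.raises(ConfigurationError, match=msg):
            FilterConfig(**kwargs)
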