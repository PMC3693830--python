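"""Fisher overrepresentation testing and q-value estimation."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from sideminer import (
    ContingencyTable,
    contingency_table,
    estimate_qvalues,
    fisher_greater,
    run_enrichment,
    select_significant,
)
from sideminer.enrichment import fisher_greater_many
from conftest import make_network


def fisher_oracle(a, b, c, d):
    """Exact-integer enumeration of same-margin tables (independent oracle)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    num = sum(comb(c1, k) * comb(n - c1, r1 - k)
              for k in range(a, min(r1, c1) + 1))
    return float(Fraction(num, comb(n, r1)))


class TestContingencyTable:
    def test_worked_example_counts(self, worked_example):
        from sideminer import build_virtual_targets

        net = build_virtual_targets(worked_example)
        t = contingency_table("ADRB1:inhibition", "C0428977", net)
        assert (t.a, t.b, t.c, t.d) == (11, 1, 173, 365)

    def test_degenerate_margins(self):
        net = make_network({"P": ["d1", "d2"]}, {"S": []})
        t = contingency_table("P:binding", "S", net)
        assert (t.a, t.b, t.c, t.d) == (0, 2, 0, 0)

    def test_margin_identities(self, default_world_result):
        n = None
        for r in default_world_result.predictions[:200]:
            t = r.table
            assert t.n_binders == t.a + t.b
            assert t.n_elicitors == t.a + t.c
            n = n or t.n
            assert t.n == n  # all tables share the active-set total

    def test_unknown_entities_raise(self):
        net = make_network({"P": ["d1"]}, {"S": ["d1"]})
        with pytest.raises(KeyError):
            contingency_table("X:binding", "S", net)
        with pytest.raises(KeyError):
            contingency_table("P:binding", "X", net)


class TestFisherGreater:
    def test_printed_worked_example(self):
        p = fisher_greater(ContingencyTable(11, 1, 173, 365))
        assert f"{p:.0e}" == "4e-05"  # one significant figure

    def test_a_zero_gives_one(self):
        assert fisher_greater(ContingencyTable(0, 5, 3, 10)) == 1.0

    def test_tiny_table_exact(self):
        assert fisher_greater(ContingencyTable(2, 0, 0, 2)) == pytest.approx(1 / 6)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = ContingencyTable(a, b, c, d)
        assert fisher_greater(t) == pytest.approx(fisher_oracle(a, b, c, d),
                                                  abs=1e-12)

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact

        for table in [(11, 1, 173, 365), (5, 10, 3, 80), (1, 1, 1, 1)]:
            t = ContingencyTable(*table)
            expected = fisher_exact(
                [[t.a, t.b], [t.c, t.d]], alternative="greater"
            ).pvalue
            assert fisher_greater(t) == pytest.approx(expected, rel=1e-10)

    def test_vectorised_path_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        n_total = 120
        m = rng.integers(1, 60, size=50)
        k = rng.integers(1, 60, size=50)
        a = np.minimum(rng.integers(1, 20, size=50), np.minimum(m, k))
        many = fisher_greater_many(a, m, k, n_total)
        for i in range(50):
            t = ContingencyTable(
                int(a[i]), int(m[i] - a[i]), int(k[i] - a[i]),
                int(n_total - m[i] - k[i] + a[i]),
            )
            assert many[i] == pytest.approx(fisher_greater(t), rel=1e-10)


class TestEstimateQvalues:
    def test_identical_pvalues_collapse_to_p(self):
        q, pi0 = estimate_qvalues([0.03] * 10, method="bh")
        assert pi0 == 1.0
        assert np.allclose(q, 0.03)

    def test_bh_step_up_by_hand(self):
        q, _ = estimate_qvalues([0.01, 0.02, 0.04, 1.0], method="bh")
        assert q == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 1.0])

    def test_bh_equals_statsmodels(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(5, 200))
            q, _ = estimate_qvalues(p, method="bh")
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, expected, atol=0, rtol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=300))
    @settings(max_examples=100, deadline=None)
    def test_q_monotone_in_p(self, pvalues):
        for method in ("bh", "storey-smoother"):
            q, pi0 = estimate_qvalues(pvalues, method=method)
            assert 0 < pi0 <= 1
            order = np.argsort(pvalues)
            assert np.all(np.diff(q[order]) >= -1e-15)
            assert np.all((q >= 0) & (q <= 1))

    def test_storey_pi0_near_one_under_null(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=5000)
        _, pi0 = estimate_qvalues(p, method="storey-smoother")
        assert pi0 > 0.8

    def test_storey_pi0_shrinks_with_signal(self):
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.uniform(size=2000),
                            rng.beta(0.1, 10, size=2000)])
        _, pi0 = estimate_qvalues(p, method="storey-smoother")
        assert pi0 < 0.8

    def test_small_sample_falls_back_to_pi0_one(self):
        _, pi0 = estimate_qvalues([0.01] * 50, method="storey-smoother")
        assert pi0 == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_qvalues([])
        with pytest.raises(ValueError):
            estimate_qvalues([0.5, 1.5])
        with pytest.raises(ValueError):
            estimate_qvalues([0.5], method="bonferroni")


class TestRunEnrichment:
    def test_planted_pair_dominates(self):
        # one causal target with full penetrance and no background noise
        drugs = [f"d{i}" for i in range(40)]
        binders = drugs[:8]
        net = make_network(
            {"P": binders, "Q": drugs[8:16]},
            {"S": binders, "T": drugs[3:20]},
        )
        records = run_enrichment(net)
        assert records[0].target.protein_id == "P"
        assert records[0].se_id == "S"
        assert records[0].p == min(r.p for r in records)

    def test_only_cooccurring_pairs_tested(self, default_world_result):
        records = default_world_result.predictions
        assert all(r.table.a >= 1 for r in records)
        net = default_world_result.network
        n_expected = 0
        for key in net.targets:
            binders = net.active_binders(key)
            for se in net.side_effects:
                if binders & net.active_elicitors(se):
                    n_expected += 1
        assert len(records) == n_expected

    def test_empty_network_errors(self):
        net = make_network({}, {})
        with pytest.raises(ValueError):
            run_enrichment(net)


class TestSelectSignificant:
    def make(self, q, excluded=False):
        from sideminer import PredictionRecord, TargetNode

        return PredictionRecord(
            target=TargetNode("P", "binding"), se_id="S",
            table=ContingencyTable(1, 1, 1, 1), p=q / 2, q=q, excluded=excluded,
        )

    def test_boundary_is_strict(self):
        assert select_significant([self.make(0.01)], 0.01) == []

    def test_below_cutoff_included(self):
        assert len(select_significant([self.make(0.009)], 0.01)) == 1

    def test_flagged_record_excluded_despite_tiny_q(self):
        assert select_significant([self.make(1e-6, excluded=True)], 0.01) == []
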