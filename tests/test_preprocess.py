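"""Virtual targets, target merging, Tanimoto/Hobohm de-redundancy, filters."""

import pytest
from hypothesis import given, settings, strategies as st

from sideminer import (
    ContingencyTable,
    Fingerprint,
    PredictionRecord,
    TargetNode,
    build_virtual_targets,
    filter_min_support,
    flag_metabolizing_exclusions,
    hobohm_reduce,
    merge_equivalent_targets,
    tanimoto,
)
from conftest import make_network


def fp(drug_id, bits, length=16):
    return Fingerprint(drug_id, frozenset(bits), length)


class TestVirtualTargets:
    def test_inhibitor_gains_virtual_node(self):
        net = make_network(
            {"P": ["d1"]}, {"S": ["d1"]}, modes={("d1", "P"): {"inhibition"}}
        )
        out = build_virtual_targets(net)
        assert out.target_drugs["P:binding"] == {"d1"}
        assert out.target_drugs["P:inhibition"] == {"d1"}

    def test_modeless_edge_stays_generic(self):
        net = make_network({"P": ["d1"]}, {"S": ["d1"]})
        out = build_virtual_targets(net)
        assert set(out.targets) == {"P:binding"}

    def test_opposite_modes_make_three_nodes(self):
        net = make_network(
            {"P": ["d1", "d2"]}, {"S": ["d1"]},
            modes={("d1", "P"): {"activation"}, ("d2", "P"): {"inhibition"}},
        )
        out = build_virtual_targets(net)
        assert set(out.targets) == {"P:binding", "P:activation", "P:inhibition"}

    def test_mode_for_absent_edge_ignored(self):
        net = make_network({"P": ["d1"]}, {"S": ["d1"]},
                           modes={("d1", "Q"): {"inhibition"}})
        out = build_virtual_targets(net)
        assert set(out.targets) == {"P:binding"}


class TestMergeEquivalentTargets:
    def test_identical_drug_sets_merge(self):
        net = make_network(
            {"P1": ["d1", "d2", "d3"], "P2": ["d1", "d2", "d3"]},
            {"S": ["d1"]},
        )
        merged, merge_map = merge_equivalent_targets(net)
        assert len(merged.targets) == 1
        (node,) = merged.targets.values()
        assert node.merged_members == {("P1", "binding"), ("P2", "binding")}

    def test_different_drug_sets_stay_apart(self):
        net = make_network({"P1": ["d1", "d2"], "P2": ["d1", "d3"]}, {"S": ["d1"]})
        merged, _ = merge_equivalent_targets(net)
        assert len(merged.targets) == 2

    def test_merge_is_partition_and_unmerge_restores_edges(self, default_world):
        net = build_virtual_targets(default_world.network)
        merged, merge_map = merge_equivalent_targets(net)
        # partition: every original node appears in exactly one merged node
        seen = [m for members in merge_map.values() for m in members]
        assert sorted(seen) == sorted(net.targets)
        # unmerge reproduces the original edge multiset
        original = {key: set(drugs) for key, drugs in net.target_drugs.items()}
        restored = {
            member: set(drugs)
            for members in merge_map.values()
            for member, drugs in members.items()
        }
        assert restored == original

    def test_drug_sets_compared_over_active_set_only(self):
        net = make_network({"P1": ["d1", "d2"], "P2": ["d1", "d2", "d3"]},
                           {"S": ["d1"]})
        net.active_drug_set = {"d1", "d2"}  # d3 removed as redundant
        merged, _ = merge_equivalent_targets(net)
        assert len(merged.targets) == 1
        (key,) = merged.targets
        assert merged.target_drugs[key] == {"d1", "d2", "d3"}  # union kept


class TestTanimoto:
    def test_identical_vectors(self):
        assert tanimoto(fp("a", {1, 5}), fp("b", {1, 5})) == 1.0

    def test_disjoint_vectors(self):
        assert tanimoto(fp("a", {1, 2}), fp("b", {3, 4})) == 0.0

    def test_partial_overlap(self):
        assert tanimoto(fp("a", {1, 2}), fp("b", {1, 3})) == pytest.approx(1 / 3)

    def test_all_zero_convention(self):
        assert tanimoto(fp("a", set()), fp("b", set())) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(fp("a", {1}, 8), fp("b", {1}, 16))

    @given(
        a=st.sets(st.integers(0, 15)),
        b=st.sets(st.integers(0, 15)),
        c=st.sets(st.integers(0, 15)),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_bounds_and_identity(self, a, b, c):
        s = tanimoto(fp("a", a), fp("b", b))
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(fp("b", b), fp("a", a))
        if a:
            assert tanimoto(fp("a", a), fp("a", a)) == 1.0


class TestHobohmReduce:
    def test_no_similar_pair_keeps_all(self):
        fps = {"A": fp("A", {1, 2}), "B": fp("B", {5, 6})}
        assert hobohm_reduce({"A", "B"}, fps, 0.7) == {"A", "B"}

    def test_hub_removed_first(self):
        # A~B and A~C above cutoff, B and C dissimilar -> A goes, B & C stay
        fps = {
            "A": fp("A", {1, 2, 3, 4, 5, 6}),
            "B": fp("B", {1, 2, 3, 4, 5, 7}),
            "C": fp("C", {2, 3, 4, 5, 6, 8}),
        }
        assert tanimoto(fps["A"], fps["B"]) > 0.7
        assert tanimoto(fps["A"], fps["C"]) > 0.7
        assert tanimoto(fps["B"], fps["C"]) <= 0.7
        assert hobohm_reduce({"A", "B", "C"}, fps, 0.7) == {"B", "C"}

    def test_clique_leaves_one(self):
        fps = {
            "A": fp("A", {1, 2, 3, 4, 5, 6, 7, 8}),
            "B": fp("B", {1, 2, 3, 4, 5, 6, 7, 9}),
            "C": fp("C", {1, 2, 3, 4, 5, 6, 7, 10}),
        }
        kept = hobohm_reduce({"A", "B", "C"}, fps, 0.7)
        assert len(kept) == 1

    def test_missing_fingerprints_kept(self):
        fps = {"A": fp("A", {1, 2})}
        assert hobohm_reduce({"A", "B"}, fps, 0.7) == {"A", "B"}

    def test_deterministic_tie_break(self):
        # identical twins: the lexicographically greater id is removed
        fps = {"A": fp("A", {1, 2, 3}), "B": fp("B", {1, 2, 3})}
        assert hobohm_reduce({"A", "B"}, fps, 0.7) == {"A"}

    @given(data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_postcondition_no_kept_pair_similar(self, data):
        n = data.draw(st.integers(2, 12))
        drugs = [f"d{i}" for i in range(n)]
        fps = {
            d: fp(d, data.draw(st.sets(st.integers(0, 11), min_size=1)), 12)
            for d in drugs
        }
        kept = hobohm_reduce(set(drugs), fps, 0.7)
        assert kept  # never empties the set
        kept_list = sorted(kept)
        for i, a in enumerate(kept_list):
            for b in kept_list[i + 1:]:
                assert tanimoto(fps[a], fps[b]) <= 0.7


class TestMinSupportFilter:
    def make(self, n_binders):
        drugs = [f"d{i}" for i in range(max(n_binders, 6))]
        return make_network(
            {"P": drugs[:n_binders], "Q": drugs[:6]},
            {"S": drugs[:6], "T": []},
        )

    def test_four_binders_removed(self):
        net = filter_min_support(self.make(4), 5)
        assert "P:binding" not in net.targets

    def test_five_binders_kept(self):
        net = filter_min_support(self.make(5), 5)
        assert "P:binding" in net.targets

    def test_empty_side_effect_removed(self):
        net = filter_min_support(self.make(6), 5)
        assert "T" not in net.side_effects
        assert "S" in net.side_effects

    def test_counts_use_active_set(self):
        net = self.make(5)
        net.active_drug_set -= {"d0"}  # P now has 4 active binders
        out = filter_min_support(net, 5)
        assert "P:binding" not in out.targets


class TestMetabolizingFlag:
    def record(self, protein, members=None):
        node = TargetNode(protein, "binding", members)
        return PredictionRecord(
            target=node, se_id="S", table=ContingencyTable(1, 1, 1, 1), p=0.5
        )

    def test_flagged_protein(self):
        r = self.record("CYP1")
        flag_metabolizing_exclusions([r], {"CYP1"})
        assert r.excluded

    def test_any_merged_member_flags(self):
        r = self.record(
            "P1", frozenset({("P1", "binding"), ("CYP9", "binding")})
        )
        flag_metabolizing_exclusions([r], {"CYP9"})
        assert r.excluded

    def test_empty_set_flags_nothing(self):
        r = self.record("CYP1")
        flag_metabolizing_exclusions([r], set())
        assert not r.excluded
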