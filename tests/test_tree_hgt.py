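"""Newick parsing, support normalization, and the topology HGT test."""

import pytest

from hgtscreen.taxonomy import Domain
from hgtscreen.tree_hgt import (
    NewickParseError,
    batch_tree_screen,
    hgt_topology_test,
    read_newick,
)

LABELS = {
    "P1": "Eukaryota",
    "P2": "Eukaryota",
    "P3": "Eukaryota",
    "B1": "Bacteria",
    "B2": "Bacteria",
    "Q": "Bacteria",
}

NESTED = "((Q,(P1,P2)0.9)0.95,(B1,B2)0.9);"
SISTER_BACT = "((Q,B1)0.99,(P1,P2)0.9);"
WEAK = "((Q,(P1,P2)0.9)0.5,(B1,B2)0.9);"


class TestReadNewick:
    def test_leaves_and_supports(self):
        t = read_newick("((A,B)0.9,(C,D)0.8);", is_string=True)
        assert sorted(t.leaf_labels) == ["A", "B", "C", "D"]
        assert t.supports == {
            frozenset({"A", "B"}): 0.9,
            frozenset({"C", "D"}): 0.8,
        }

    def test_percent_scale_normalized(self):
        t = read_newick("((A,B)95,(C,D)80);", is_string=True)
        assert sorted(t.supports.values()) == [0.80, 0.95]

    def test_mixed_scales_rejected(self):
        with pytest.raises(NewickParseError, match="mixed"):
            read_newick("((A,B)95,(C,D)0.8);", is_string=True)

    def test_unbalanced_parentheses(self):
        with pytest.raises(NewickParseError):
            read_newick("((A,B;", is_string=True)

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(NewickParseError, match="duplicate"):
            read_newick("((A,A),B);", is_string=True)

    def test_missing_supports_absent_not_zero(self):
        t = read_newick("((A,B),(C,D)0.7);", is_string=True)
        assert frozenset({"A", "B"}) not in t.supports


class TestHgtTopologyTest:
    @pytest.mark.parametrize(
        "newick,verdict",
        [
            (NESTED, "hgt_consistent"),
            (SISTER_BACT, "not_consistent"),
            (WEAK, "unsupported"),
        ],
    )
    def test_three_canonical_patterns(self, newick, verdict):
        t = read_newick(newick, is_string=True)
        call = hgt_topology_test(t, "Q", LABELS)
        assert call.verdict == verdict

    def test_consistent_call_details(self):
        call = hgt_topology_test(read_newick(NESTED, is_string=True), "Q", LABELS)
        assert call.supporting_clade == ("P1", "P2")
        assert call.clade_support == pytest.approx(0.95)
        assert call.alien_purity == 1.0

    def test_query_absent(self):
        t = read_newick("((A,B)0.9,(C,D)0.9);", is_string=True)
        labels = {x: "Bacteria" for x in "ABCD"}
        assert hgt_topology_test(t, "Q", labels).verdict == "query_absent"

    def test_rotation_invariance(self):
        rotations = [
            NESTED,
            "((B2,B1)0.9,((P2,P1)0.9,Q)0.95);",
            "(((P1,P2)0.9,Q)0.95,(B1,B2)0.9);",
        ]
        verdicts = {
            hgt_topology_test(read_newick(n, is_string=True), "Q", LABELS).verdict
            for n in rotations
        }
        assert verdicts == {"hgt_consistent"}

    def test_relaxing_s_min_upgrades_unsupported(self):
        t = read_newick(WEAK, is_string=True)
        assert hgt_topology_test(t, "Q", LABELS, s_min=0.0).verdict == "hgt_consistent"

    @pytest.mark.parametrize("newick", [NESTED, SISTER_BACT, WEAK])
    def test_monotone_strictness(self, newick):
        """Raising s_min or p_min never turns not_consistent into hgt_consistent."""
        t = read_newick(newick, is_string=True)
        rank = {"hgt_consistent": 2, "unsupported": 1, "not_consistent": 0,
                "query_absent": 0}
        prev = None
        for s_min in (0.0, 0.5, 0.9, 1.0):
            v = hgt_topology_test(t, "Q", LABELS, s_min=s_min).verdict
            if prev is not None:
                assert rank[v] <= rank[prev]
            prev = v
        base = hgt_topology_test(t, "Q", LABELS, p_min=0.5).verdict
        strict = hgt_topology_test(t, "Q", LABELS, p_min=1.0).verdict
        assert rank[strict] <= rank[base]

    def test_mixed_clade_purity_below_one(self):
        # clade containing Q holds one plant and one bacterium: purity 0.5
        t = read_newick("((Q,(P1,B1)0.9)0.95,(P2,B2)0.9);", is_string=True)
        call = hgt_topology_test(t, "Q", LABELS)
        assert call.alien_purity == pytest.approx(0.5)
        assert call.verdict == "not_consistent"
        assert hgt_topology_test(t, "Q", LABELS, p_min=0.5).verdict == "hgt_consistent"

    def test_unmapped_leaf_raises(self):
        t = read_newick(NESTED, is_string=True)
        with pytest.raises(KeyError, match="P2"):
            hgt_topology_test(t, "Q", {k: v for k, v in LABELS.items() if k != "P2"})

    def test_outgroup_rooting(self):
        # unrooted-style reading: rooting on the bacterial outgroup leaves the
        # plant clade containing Q intact
        t = read_newick("(Q,(P1,P2)0.9,(B1,B2)0.95);", is_string=True)
        call = hgt_topology_test(t, "Q", LABELS, outgroup=["B1", "B2"])
        assert call.verdict in ("hgt_consistent", "unsupported")


class TestBatchScreen:
    def test_three_verdicts_and_one_corrupt_file(self, tmp_path):
        (tmp_path / "a_nested.nwk").write_text(NESTED)
        (tmp_path / "b_sister.nwk").write_text(SISTER_BACT)
        (tmp_path / "c_weak.nwk").write_text(WEAK)
        (tmp_path / "d_corrupt.nwk").write_text("((A,B;")
        table = batch_tree_screen(tmp_path, LABELS, query_label="Q")
        assert len(table) == 4
        by_file = dict(zip(table["tree"], table["verdict"]))
        assert by_file["a_nested.nwk"] == "hgt_consistent"
        assert by_file["b_sister.nwk"] == "not_consistent"
        assert by_file["c_weak.nwk"] == "unsupported"
        assert by_file["d_corrupt.nwk"] == "read_error"
        assert (table["verdict"] != "read_error").sum() == 3

    def test_query_inferred_as_unique_focal_leaf(self, tmp_path):
        (tmp_path / "t.nwk").write_text("((QX,(P1,P2)0.9)0.95,(P3,P1b)0.9);")
        labels = {
            "P1": "Eukaryota",
            "P2": "Eukaryota",
            "P3": "Eukaryota",
            "P1b": "Eukaryota",
            "QX": "Bacteria",
        }
        table = batch_tree_screen(tmp_path, labels, focal=Domain.BACTERIA)
        assert list(table["query"]) == ["QX"]
        assert list(table["verdict"]) == ["hgt_consistent"]

    def test_empty_directory(self, tmp_path):
        table = batch_tree_screen(tmp_path, LABELS)
        assert len(table) == 0


class TestSimulatedTrees:
    def test_donor_and_recipient_placements(self):
        from hgtscreen.synthetic_data import simulate_hgt_tree

        for seed in range(5):
            sim = simulate_hgt_tree(place_query="donor", seed=seed)
            t = read_newick(sim.newick, is_string=True)
            assert (
                hgt_topology_test(t, sim.query_label, sim.label_map).verdict
                == "hgt_consistent"
            )
            sim = simulate_hgt_tree(place_query="recipient", seed=seed)
            t = read_newick(sim.newick, is_string=True)
            assert (
                hgt_topology_test(t, sim.query_label, sim.label_map).verdict
                == "not_consistent"
            )
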