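"""Hit-table parsing, alien fractions, candidate rule, pairwise identity."""

import math

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from hgtscreen.hit_screen import (
    HitTable,
    HitTableParseError,
    alien_fraction,
    pairwise_identity,
    read_hit_table,
    screen_proteome,
    write_hit_table,
)
from hgtscreen.taxonomy import Domain, is_alien


def _row(query, subject, taxid, bitscore=100.0):
    return (
        f"{query}\t{subject}\t50.0\t120\t40\t2\t1\t120\t5\t124\t1e-30\t{bitscore}"
        f"\t{taxid}\n"
    )


class TestReadHitTable:
    def test_groups_by_query_preserving_order(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            _row("q1", "s1", "b1")
            + _row("q1", "s2", "p1")
            + _row("q2", "s3", "p2")
            + _row("q1", "s4", "p3")
            + _row("q2", "s5", "b2")
        )
        table = read_hit_table(p)
        assert table.n_queries == 2
        assert table.n_hits == 5
        assert [h.subject_id for h in table.queries["q1"]] == ["s1", "s2", "s4"]

    def test_comment_lines_are_skipped(self, tmp_path):
        body = _row("q1", "s1", "b1") + _row("q1", "s2", "p1")
        plain = tmp_path / "plain.tsv"
        plain.write_text(body)
        commented = tmp_path / "commented.tsv"
        commented.write_text("# BLASTP 2.x\n# Fields: ...\n" + body)
        assert (
            read_hit_table(plain).queries == read_hit_table(commented).queries
        )

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(_row("q1", "s1", "b1") + "q2\ts2\t" + "\t".join(["1"] * 9) + "\n")
        with pytest.raises(HitTableParseError, match=":2"):
            read_hit_table(p)

    def test_roundtrip_through_writer(self, tmp_path, hit_factory):
        table = HitTable()
        for i in range(4):
            table.add(hit_factory(query="qX", subject=f"s{i}", bitscore=90.0 - i))
        path = write_hit_table(table, tmp_path / "out.tsv")
        back = read_hit_table(path)
        assert back.n_hits == 4
        assert [h.bitscore for h in back.queries["qX"]] == [90.0, 89.0, 88.0, 87.0]


class TestAlienFraction:
    def test_all_focal_is_zero(self, toy_lineages, hit_factory):
        hits = [hit_factory(subject=f"s{i}", taxon="b1") for i in range(10)]
        frac, c = alien_fraction(hits, toy_lineages)
        assert frac == 0.0
        assert (c.n_alien, c.n_focal, c.n_excluded) == (0, 10, 0)

    def test_eight_of_ten_alien(self, toy_lineages, hit_factory):
        hits = [hit_factory(subject=f"s{i}", taxon="p1") for i in range(8)]
        hits += [hit_factory(subject=f"t{i}", taxon="b1") for i in range(2)]
        frac, _ = alien_fraction(hits, toy_lineages)
        assert frac == pytest.approx(0.8)

    def test_unknown_excluded_from_denominator(self, toy_lineages, hit_factory):
        hits = [hit_factory(subject=f"s{i}", taxon="p1") for i in range(7)]
        hits += [hit_factory(subject=f"t{i}", taxon="b1") for i in range(2)]
        hits += [hit_factory(subject="u", taxon="ghost")]
        frac, c = alien_fraction(hits, toy_lineages)
        assert frac == pytest.approx(7 / 9)
        assert c.n_excluded == 1

    def test_self_taxa_removed_before_counting(self, toy_lineages, hit_factory):
        hits = [hit_factory(subject=f"s{i}", taxon="p1") for i in range(4)]
        hits += [hit_factory(subject=f"me{i}", taxon="b3") for i in range(6)]
        frac, c = alien_fraction(hits, toy_lineages, self_taxa={"b3"})
        assert c.n_self == 6
        assert frac == 1.0

    def test_max_hits_keeps_best_by_bitscore(self, toy_lineages, hit_factory):
        # 3 alien hits at high bitscore, 3 focal at low: cap at 3 keeps aliens
        hits = [
            hit_factory(subject=f"a{i}", taxon="p1", bitscore=200.0 + i)
            for i in range(3)
        ]
        hits += [
            hit_factory(subject=f"f{i}", taxon="b1", bitscore=50.0 + i)
            for i in range(3)
        ]
        frac, _ = alien_fraction(hits, toy_lineages, max_hits=3)
        assert frac == 1.0

    def test_mixed_queries_rejected(self, toy_lineages, hit_factory):
        hits = [hit_factory(query="q1"), hit_factory(query="q2")]
        with pytest.raises(ValueError, match="single query"):
            alien_fraction(hits, toy_lineages)

    @settings(deadline=None, max_examples=200,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(
        st.lists(
            st.sampled_from(["b1", "b2", "b3", "p1", "p2", "p3", "f1", "a1", "zz"]),
            min_size=1,
            max_size=30,
        )
    )
    def test_matches_bruteforce_count(self, toy_lineages, hit_factory, taxa):
        """The vectorised path equals a per-hit brute-force count."""
        hits = [hit_factory(subject=f"s{i}", taxon=t) for i, t in enumerate(taxa)]
        frac, c = alien_fraction(hits, toy_lineages)
        calls = [is_alien(t, Domain.BACTERIA, toy_lineages) for t in taxa]
        n_alien = calls.count("alien")
        n_focal = calls.count("focal")
        assert (c.n_alien, c.n_focal) == (n_alien, n_focal)
        if n_alien + n_focal == 0:
            assert frac is None
        else:
            assert frac == pytest.approx(n_alien / (n_alien + n_focal))
            assert 0.0 <= frac <= 1.0

    def test_monotonicity(self, toy_lineages, hit_factory):
        hits = [hit_factory(subject=f"s{i}", taxon="p1") for i in range(3)]
        hits += [hit_factory(subject=f"t{i}", taxon="b1") for i in range(3)]
        base, _ = alien_fraction(hits, toy_lineages)
        plus_alien, _ = alien_fraction(
            hits + [hit_factory(subject="x", taxon="p2")], toy_lineages
        )
        plus_focal, _ = alien_fraction(
            hits + [hit_factory(subject="x", taxon="b2")], toy_lineages
        )
        assert plus_alien >= base >= plus_focal


class TestScreenProteome:
    def _table(self, hit_factory, spec):
        """spec: {query: (n_alien, n_focal)}"""
        t = HitTable()
        for q, (na, nf) in spec.items():
            for i in range(na):
                t.add(hit_factory(query=q, subject=f"{q}a{i}", taxon="p1"))
            for i in range(nf):
                t.add(hit_factory(query=q, subject=f"{q}f{i}", taxon="b1"))
        return t

    def test_threshold_is_inclusive_at_080(self, toy_lineages, hit_factory):
        table = self._table(hit_factory, {"at": (8, 2), "below": (79, 21)})
        res = {r.query_id: r for r in screen_proteome(table, toy_lineages)}
        assert res["at"].alien_fraction == pytest.approx(0.80)
        assert res["at"].candidate is True
        assert res["below"].alien_fraction == pytest.approx(0.79)
        assert res["below"].candidate is False

    def test_insufficient_hits(self, toy_lineages, hit_factory):
        table = self._table(hit_factory, {"tiny": (3, 0)})
        (r,) = screen_proteome(table, toy_lineages, min_hits=5)
        assert r.status == "insufficient_hits"
        assert r.candidate is False
        assert math.isnan(r.alien_fraction)

    def test_sorted_by_descending_fraction_then_id(self, toy_lineages, hit_factory):
        table = self._table(
            hit_factory,
            {"qb": (9, 1), "qa": (9, 1), "low": (1, 9), "mid": (5, 5), "tiny": (1, 0)},
        )
        res = screen_proteome(table, toy_lineages)
        assert [r.query_id for r in res] == ["qa", "qb", "mid", "low", "tiny"]

    def test_tau_out_of_range(self, toy_lineages, hit_factory):
        table = self._table(hit_factory, {"q": (5, 5)})
        with pytest.raises(ValueError, match="tau"):
            screen_proteome(table, toy_lineages, tau=1.5)

    def test_empty_table(self, toy_lineages):
        assert screen_proteome(HitTable(), toy_lineages) == []


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        r = pairwise_identity("MKVLITGAGQR", "MKVLITGAGQR")
        assert r.percent_identity == 100.0
        assert r.percent_coverage == 100.0

    def test_three_of_four_columns(self):
        r = pairwise_identity("ACDE", "ACDF")
        assert r.percent_identity == 75.0
        assert r.n_columns == 4

    def test_similarity_counts_positive_scores(self):
        # D vs E scores +2 in BLOSUM62: similar but not identical
        r = pairwise_identity("AAD", "AAE")
        assert r.percent_identity == pytest.approx(66.7)
        assert r.percent_similarity == 100.0

    @pytest.mark.parametrize("a,b", [("", "ACD"), ("ACD", ""), ("AC1D", "ACD")])
    def test_invalid_sequences_rejected(self, a, b):
        with pytest.raises(ValueError):
            pairwise_identity(a, b)

    def test_local_mode_ignores_flanks(self):
        r = pytest.approx(100.0)
        res = pairwise_identity("GGGGWCDEYWGGGG", "WCDEYW", mode="local")
        assert res.percent_identity == r
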