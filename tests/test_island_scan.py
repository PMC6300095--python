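"""Compositional scanning, region calling, and interval containment."""

import numpy as np
import pytest

from hgtscreen.bplea import (
    BPLEA_GENES,
    PREDICTED_ISLANDS,
    bplea_containment_table,
)
from hgtscreen.island_scan import (
    GenomicInterval,
    WindowScoreTrack,
    call_alien_regions,
    gene_island_overlap,
    read_gene_intervals,
    scan_sequence,
    write_regions_gff3,
)


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("c", 10, 5)
        with pytest.raises(ValueError):
            GenomicInterval("c", 0, 5)

    def test_arithmetic(self):
        a = GenomicInterval("c", 100, 199)
        b = GenomicInterval("c", 150, 250)
        assert a.length == 100
        assert a.overlap_bp(b) == 50
        assert a.jaccard(b) == pytest.approx(50 / 151)
        assert GenomicInterval("c", 90, 300).contains(a)
        assert not a.contains(b)
        # 1-based inclusive: [100,199] and [200,...] abut with distance 1
        assert a.boundary_distance(GenomicInterval("c", 205, 300)) == 6
        assert a.overlap_bp(GenomicInterval("other", 100, 199)) == 0


class TestScan:
    def test_geometry_errors(self):
        with pytest.raises(ValueError, match="w=3"):
            scan_sequence("ACGT" * 100, w=3, k=4)
        with pytest.raises(ValueError, match="shorter"):
            scan_sequence("ACGTACGT", w=100)

    def test_iid_uniform_genome_has_no_extreme_windows(self):
        rng = np.random.default_rng(42)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
        track = scan_sequence(seq)
        assert track.n_windows == 39
        assert float(track.zscores.max()) < 4.0
        # z-scores are standardized against the track itself
        assert float(np.mean(track.zscores)) == pytest.approx(0.0, abs=1e-12)

    def test_planted_island_is_argmax_window(self):
        from hgtscreen.synthetic_data import simulate_genome_with_island

        sim = simulate_genome_with_island(seed=11)
        track = scan_sequence(sim.sequence, sim.contig_id)
        i = int(np.argmax(track.zscores))
        window = GenomicInterval(
            sim.contig_id,
            int(track.starts[i]),
            int(track.starts[i]) + track.window_size - 1,
        )
        assert window.overlap_bp(sim.island) > 0

    def test_ambiguity_codes_are_skipped(self):
        rng = np.random.default_rng(0)
        seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 20_000)]))
        for i in range(0, len(seq), 97):
            seq[i] = "N"
        track = scan_sequence("".join(seq), w=5000, s=2500)
        assert np.all(np.isfinite(track.scores))


class TestCallRegions:
    def _track(self, z):
        z = np.asarray(z, dtype=float)
        starts = np.arange(len(z)) * 2500 + 1
        return WindowScoreTrack("c", 5000, 2500, 4, starts, z.copy(), z)

    def test_no_window_above_threshold(self):
        assert call_alien_regions(self._track([0, 1, 2, 3]), z_min=4.0) == []

    def test_adjacent_windows_merge(self):
        regions = call_alien_regions(self._track([0, 5, 5, 0]), z_min=4.0)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (2501, 10000)

    def test_merge_gap_of_one_window(self):
        # one sub-threshold window between two calls still merges at gap 1
        regions = call_alien_regions(self._track([5, 0, 5, 0, 0, 5]), z_min=4.0)
        assert len(regions) == 2
        regions0 = call_alien_regions(
            self._track([5, 0, 5, 0, 0, 5]), z_min=4.0, merge_gap=0
        )
        assert len(regions0) == 3

    def test_regions_disjoint_and_sorted(self):
        regions = call_alien_regions(self._track([5, 0, 0, 5, 5, 0, 0, 5]), 4.0)
        for a, b in zip(regions, regions[1:]):
            assert a.end < b.start

    def test_planted_island_recovery(self):
        from hgtscreen.synthetic_data import simulate_genome_with_island

        sim = simulate_genome_with_island(seed=11)
        track = scan_sequence(sim.sequence, sim.contig_id)
        regions = call_alien_regions(track)
        assert len(regions) == 1
        assert regions[0].jaccard(sim.island) >= 0.5


class TestGeneIslandOverlap:
    def test_contained(self):
        gene = GenomicInterval("NZ_KK037166", 488_980, 489_726)
        region = GenomicInterval("NZ_KK037166", 487_500, 492_500)
        rep = gene_island_overlap(gene, [region])
        assert rep.relation == "contained"
        assert rep.overlap_bp == gene.length

    def test_disjoint_with_distance(self):
        gene = GenomicInterval("BCMK01000043", 18_945, 19_709)
        region = GenomicInterval("BCMK01000043", 22_500, 27_500)
        rep = gene_island_overlap(gene, [region])
        assert rep.relation == "disjoint"
        assert rep.overlap_bp == 0
        assert rep.nearest_distance_bp == 2_791

    def test_partial(self):
        gene = GenomicInterval("c", 100, 200)
        rep = gene_island_overlap(gene, [GenomicInterval("c", 150, 500)])
        assert rep.relation == "partial"
        assert rep.overlap_bp == 51

    def test_contig_mismatch_is_error(self):
        gene = GenomicInterval("c1", 1, 10)
        with pytest.raises(ValueError, match="contig"):
            gene_island_overlap(gene, [GenomicInterval("c2", 1, 10)])

    def test_no_regions(self):
        rep = gene_island_overlap(GenomicInterval("c", 1, 10), [])
        assert rep.relation == "disjoint"
        assert rep.best_region is None


class TestPublishedContainmentPattern:
    """The three BPLEA genes against the six published predicted regions."""

    EXPECTED = {
        ("IQ63_RS07865", "alien_hunter"): "contained",
        ("IQ63_RS07865", "islandviewer4"): "disjoint",
        ("a10_05000", "alien_hunter"): "disjoint",
        ("a10_05000", "islandviewer4"): "disjoint",
        ("KUTG_RS02170", "alien_hunter"): "contained",
        ("KUTG_RS02170", "islandviewer4"): "contained",
    }

    def test_relation_matrix(self):
        table = bplea_containment_table()
        assert len(table) == 6
        got = {
            (row["gene"], row["predictor"]): row["relation"]
            for _, row in table.iterrows()
        }
        assert got == self.EXPECTED

    def test_a10_nearest_distance(self):
        gene = BPLEA_GENES["a10_05000"]
        region = PREDICTED_ISLANDS[("BCMK01000043", "alien_hunter")]
        rep = gene_island_overlap(gene, [region])
        assert rep.nearest_distance_bp == 2_791


class TestIO:
    def test_bed_zero_based_conversion(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t99\t200\tgeneA\nchr1\t0\t10\tgeneB\n")
        genes = {g.label: g for g in read_gene_intervals(bed)}
        assert (genes["geneA"].start, genes["geneA"].end) == (100, 200)
        assert (genes["geneB"].start, genes["geneB"].end) == (1, 10)

    def test_gff3_roundtrip(self, tmp_path):
        regions = [
            GenomicInterval("ctg", 1_000, 5_000, "isl1"),
            GenomicInterval("ctg", 9_000, 12_000, "isl2"),
        ]
        path = write_regions_gff3(regions, tmp_path / "islands.gff3")
        back = read_gene_intervals(path, feature_types=("genomic_island",))
        assert [(g.start, g.end) for g in back] == [(1_000, 5_000), (9_000, 12_000)]
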