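"""Published coordinates for the BPLEA worked example.

BPLEA ("bacterial plant-like expansin A") denotes the plant-like expansins
of *Streptomyces acidiscabies* and *Kutzneria* sp. 744.  The coordinates
below are the published gene positions of the three BPLEA genes on their
genomic contigs, together with the genomic-island regions predicted around
them by two external compositional predictors (Alien_Hunter and
IslandViewer4).  They drive the containment worked example: interval
arithmetic alone decides which genes fall inside which predicted regions.
"""

from __future__ import annotations

import pandas as pd

from .island_scan import GenomicInterval, gene_island_overlap

__all__ = [
    "BPLEA_GENES",
    "PREDICTED_ISLANDS",
    "PREDICTORS",
    "bplea_containment_table",
]

#: BPLEA gene positions (locus id -> interval), 1-based inclusive.
BPLEA_GENES: dict[str, GenomicInterval] = {
    "IQ63_RS07865": GenomicInterval("NZ_KQ257808", 47_596, 48_366, "IQ63_RS07865"),
    "a10_05000": GenomicInterval("BCMK01000043", 18_945, 19_709, "a10_05000"),
    "KUTG_RS02170": GenomicInterval("NZ_KK037166", 488_980, 489_726, "KUTG_RS02170"),
}

#: Species owning each contig, for reporting.
CONTIG_SPECIES: dict[str, str] = {
    "NZ_KQ257808": "S. acidiscabies NCPPB 4445",
    "BCMK01000043": "S. acidiscabies a10",
    "NZ_KK037166": "Kutzneria sp. 744",
}

PREDICTORS = ("alien_hunter", "islandviewer4")

#: Predicted island region nearest to (or containing) each BPLEA gene,
#: per predictor, as published.
PREDICTED_ISLANDS: dict[tuple[str, str], GenomicInterval] = {
    ("NZ_KQ257808", "alien_hunter"): GenomicInterval("NZ_KQ257808", 45_000, 50_000),
    ("NZ_KQ257808", "islandviewer4"): GenomicInterval("NZ_KQ257808", 21_391, 37_030),
    ("BCMK01000043", "alien_hunter"): GenomicInterval("BCMK01000043", 22_500, 27_500),
    ("BCMK01000043", "islandviewer4"): GenomicInterval("BCMK01000043", 74_467, 77_970),
    ("NZ_KK037166", "alien_hunter"): GenomicInterval("NZ_KK037166", 487_500, 492_500),
    ("NZ_KK037166", "islandviewer4"): GenomicInterval("NZ_KK037166", 465_288, 531_136),
}


def bplea_containment_table() -> pd.DataFrame:
    """Gene-vs-region relation for every (BPLEA gene, predictor) pair.

    Columns: species, contig, gene, predictor, region coordinates, the
    relation (contained/partial/disjoint) and, when disjoint, the distance
    from the gene to the nearest region boundary.
    """
    rows = []
    for locus, gene in BPLEA_GENES.items():
        for predictor in PREDICTORS:
            region = PREDICTED_ISLANDS[(gene.contig_id, predictor)]
            rep = gene_island_overlap(gene, [region])
            rows.append(
                {
                    "species": CONTIG_SPECIES[gene.contig_id],
                    "contig": gene.contig_id,
                    "gene": locus,
                    "gene_start": gene.start,
                    "gene_end": gene.end,
                    "predictor": predictor,
                    "region_start": region.start,
                    "region_end": region.end,
                    "relation": rep.relation,
                    "overlap_bp": rep.overlap_bp,
                    "nearest_distance_bp": rep.nearest_distance_bp,
                }
            )
    return pd.DataFrame(rows)
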