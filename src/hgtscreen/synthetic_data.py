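"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the screen can be exercised without downloads: this module
generates lineage tables, homology hit tables with planted high-alien-
fraction queries, genomes with compositionally divergent planted islands
containing a planted gene, and gene trees with the query leaf grafted into
a donor or recipient clade — each with a ground-truth record for recovery
tests, and byte-identical outputs for a given seed.

Default condition choices:

* hit tables: 1,000 queries (950 background, 50 planted), 20–100 hits per
  query; background alien fractions ~ Beta(1, 19) (mean 0.05), planted
  ~ Beta(23, 2) (mean 0.92) — the two distributions straddle the 0.8
  candidate threshold with margin on both sides;
* genomes: 100 kb, order-2 Markov background at GC 0.70 (actinobacterial
  base composition, with short-range autocorrelation so the scanner is not
  tested against an unrealistically white background), a 5 kb island at
  GC 0.30 containing a 750 bp gene (the scale of an expansin ORF);
* trees: two clades of 8 leaves (donor = plant-labelled, recipient =
  bacterial), internal supports ~ Uniform(0.9, 1.0), a long stem between
  the clades so midpoint rooting is unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .hit_screen import HitTable, HomologyHit, write_hit_table
from .island_scan import GenomicInterval
from .taxonomy import LineageTable, write_lineage_tsv

__all__ = [
    "TaxonomySim",
    "HitTableSim",
    "GenomeSim",
    "TreeSim",
    "simulate_taxonomy",
    "simulate_hit_tables",
    "simulate_genome_with_island",
    "simulate_background_genome",
    "simulate_hgt_tree",
    "simulate_bundle",
]

BASES = np.array(list("ACGT"))


# --------------------------------------------------------------------------
# taxonomy
# --------------------------------------------------------------------------


@dataclass
class TaxonomySim:
    """A simulated lineage table with its group membership."""

    table: LineageTable
    bacteria: list[str]
    plants: list[str]
    fungi: list[str]
    other: list[str]
    seed: int

    @property
    def aliens(self) -> list[str]:
        return self.plants + self.fungi + self.other


def simulate_taxonomy(
    n_bacteria: int = 50,
    n_plants: int = 50,
    n_fungi: int = 0,
    n_other: int = 0,
    seed: int = 0,
    path: Optional[Union[str, Path]] = None,
) -> TaxonomySim:
    """Deterministic flat lineage table with the requested group sizes.

    Taxon ids are sequential and reproducible; ``path`` additionally writes
    the flat-TSV dialect that :func:`hgtscreen.taxonomy.load_lineages` reads.
    """
    for name, n in (
        ("n_bacteria", n_bacteria),
        ("n_plants", n_plants),
        ("n_fungi", n_fungi),
        ("n_other", n_other),
    ):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_bacteria + n_plants + n_fungi + n_other < 2:
        raise ValueError("need at least 2 taxa in total")

    table = LineageTable()
    groups: dict[str, list[str]] = {"bacteria": [], "plants": [], "fungi": [], "other": []}
    i = 0

    def _add(group: str, lineage: list[tuple[str, str]]) -> None:
        nonlocal i
        i += 1
        tid = f"tax{seed % 1000:03d}{i:05d}"
        table.add(tid, lineage)
        groups[group].append(tid)

    for j in range(n_bacteria):
        _add(
            "bacteria",
            [
                ("superkingdom", "Bacteria"),
                ("phylum", "Actinomycetota"),
                ("genus", "Streptomyces"),
                ("species", f"Streptomyces sim{j + 1}"),
            ],
        )
    for j in range(n_plants):
        _add(
            "plants",
            [
                ("superkingdom", "Eukaryota"),
                ("kingdom", "Viridiplantae"),
                ("genus", "Arabidopsis"),
                ("species", f"Arabidopsis sim{j + 1}"),
            ],
        )
    for j in range(n_fungi):
        _add(
            "fungi",
            [
                ("superkingdom", "Eukaryota"),
                ("kingdom", "Fungi"),
                ("genus", "Aspergillus"),
                ("species", f"Aspergillus sim{j + 1}"),
            ],
        )
    for j in range(n_other):
        _add(
            "other",
            [
                ("superkingdom", "Archaea"),
                ("phylum", "Euryarchaeota"),
                ("species", f"Archaeon sim{j + 1}"),
            ],
        )
    sim = TaxonomySim(
        table, groups["bacteria"], groups["plants"], groups["fungi"], groups["other"], seed
    )
    if path is not None:
        write_lineage_tsv(table, path)
    return sim


# --------------------------------------------------------------------------
# hit tables
# --------------------------------------------------------------------------


@dataclass
class HitTableSim:
    """A simulated hit table plus its planted-query ground truth."""

    hit_table: HitTable
    taxonomy: TaxonomySim
    truth: list[dict]  # one record per query
    seed: int

    @property
    def planted_ids(self) -> set[str]:
        return {t["query_id"] for t in self.truth if t["planted"]}


def simulate_hit_tables(
    n_background: int = 950,
    n_planted: int = 50,
    hits_per_query: tuple[int, int] = (20, 100),
    alien_frac_background: tuple[float, float] = (1.0, 19.0),
    alien_frac_planted: tuple[float, float] = (23.0, 2.0),
    taxonomy: Optional[TaxonomySim] = None,
    seed: int = 0,
    path: Optional[Union[str, Path]] = None,
    truth_path: Optional[Union[str, Path]] = None,
) -> HitTableSim:
    """Simulate per-query homology hits with planted HGT-like queries.

    Each query draws a true alien fraction from a Beta distribution
    (background vs planted parameters) and each of its hits is alien with
    that probability; alien hits take plant/fungal/archaeal taxa, focal
    hits bacterial taxa.  Bitscores decrease down each query's hit list.
    The truth records every query's sampled and realized fraction.
    """
    if n_background < 0 or n_planted < 0 or n_background + n_planted == 0:
        raise ValueError("need a non-negative, non-empty query set")
    lo, hi = hits_per_query
    if not (1 <= lo <= hi):
        raise ValueError(f"bad hits_per_query range {hits_per_query}")

    rng = np.random.default_rng(seed)
    if taxonomy is None:
        taxonomy = simulate_taxonomy(50, 40, 5, 5, seed=seed)
    aliens = taxonomy.aliens
    focal_pool = taxonomy.bacteria

    n_total = n_background + n_planted
    planted_mask = np.zeros(n_total, dtype=bool)
    planted_mask[rng.choice(n_total, size=n_planted, replace=False)] = True

    table = HitTable()
    truth = []
    for qi in range(n_total):
        qid = f"q{qi + 1:05d}"
        planted = bool(planted_mask[qi])
        a, b = alien_frac_planted if planted else alien_frac_background
        frac = float(rng.beta(a, b))
        n_hits = int(rng.integers(lo, hi + 1))
        alien_draws = rng.random(n_hits) < frac
        if alien_draws.any() and not aliens:
            raise ValueError("alien taxon pool is empty but alien hits are required")
        if (~alien_draws).any() and not focal_pool:
            raise ValueError("focal taxon pool is empty but focal hits are required")
        bitscore = 500.0
        n_alien = 0
        for hj in range(n_hits):
            is_alien_hit = bool(alien_draws[hj])
            pool = aliens if is_alien_hit else focal_pool
            taxon = pool[int(rng.integers(len(pool)))]
            n_alien += is_alien_hit
            bitscore -= float(rng.uniform(0.5, 4.0))
            table.add(
                HomologyHit(
                    query_id=qid,
                    subject_id=f"s{qi + 1:05d}_{hj + 1:03d}",
                    taxon_id=taxon,
                    percent_identity=float(np.round(rng.uniform(30.0, 95.0), 1)),
                    alignment_length=int(rng.integers(80, 400)),
                    evalue=float(10.0 ** (-bitscore / 25.0)),
                    bitscore=round(bitscore, 1),
                )
            )
        truth.append(
            {
                "query_id": qid,
                "planted": planted,
                "true_fraction": round(frac, 6),
                "realized_fraction": round(n_alien / n_hits, 6),
                "n_hits": n_hits,
            }
        )
    sim = HitTableSim(table, taxonomy, truth, seed)
    if path is not None:
        write_hit_table(table, path)
    if truth_path is not None:
        Path(truth_path).write_text(
            json.dumps({"seed": seed, "queries": truth}, indent=1) + "\n",
            encoding="utf-8",
        )
    return sim


# --------------------------------------------------------------------------
# genomes
# --------------------------------------------------------------------------


def _markov_sequence(
    rng: np.random.Generator,
    length: int,
    gc: float,
    copy1: float = 0.15,
    copy2: float = 0.10,
) -> np.ndarray:
    """Order-2 base chain with exact stationary GC content ``gc``.

    Each position either copies the base one or two steps back (with
    probabilities ``copy1`` / ``copy2``, creating short-range
    autocorrelation) or draws i.i.d. from the stationary distribution —
    copying preserves the marginal composition exactly.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    iid = rng.choice(4, size=length, p=p)
    mode = rng.random(length)
    seq = iid.copy()
    for t in range(length):
        if t >= 1 and mode[t] < copy1:
            seq[t] = seq[t - 1]
        elif t >= 2 and mode[t] < copy1 + copy2:
            seq[t] = seq[t - 2]
    return seq


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[codes])


@dataclass
class GenomeSim:
    """A simulated contig with (optionally) a planted island and gene."""

    contig_id: str
    sequence: str
    island: Optional[GenomicInterval]
    gene: Optional[GenomicInterval]
    seed: int

    @property
    def truth(self) -> dict:
        return {
            "contig_id": self.contig_id,
            "length": len(self.sequence),
            "island": None
            if self.island is None
            else {"start": self.island.start, "end": self.island.end},
            "gene": None
            if self.gene is None
            else {"start": self.gene.start, "end": self.gene.end},
            "seed": self.seed,
        }


def simulate_background_genome(
    L: int = 100_000,
    gc: float = 0.70,
    seed: int = 0,
    contig_id: str = "sim_contig",
) -> GenomeSim:
    """A homogeneous (island-free) background contig."""
    if L < 10:
        raise ValueError("genome length too small")
    rng = np.random.default_rng(seed)
    seq = _codes_to_str(_markov_sequence(rng, L, gc))
    return GenomeSim(contig_id, seq, None, None, seed)


def simulate_genome_with_island(
    L: int = 100_000,
    island_len: int = 5_000,
    gene_len: int = 750,
    gc_background: float = 0.70,
    gc_island: float = 0.30,
    seed: int = 0,
    contig_id: str = "sim_contig",
    fasta_path: Optional[Union[str, Path]] = None,
    gff_path: Optional[Union[str, Path]] = None,
    truth_path: Optional[Union[str, Path]] = None,
) -> GenomeSim:
    """Background contig with one compositionally divergent planted island.

    The island (i.i.d. at ``gc_island``) replaces the middle of an order-2
    Markov background at ``gc_background``; a gene interval is placed
    uniformly inside the island.  Coordinates are 1-based inclusive and the
    final contig length is exactly ``L``.
    """
    if island_len <= 0 or island_len + 2 >= L:
        raise ValueError(f"island length {island_len} impossible in genome of {L} bp")
    if gene_len <= 0 or gene_len > island_len:
        raise ValueError(
            f"gene length {gene_len} must be in [1, island length {island_len}]"
        )
    rng = np.random.default_rng(seed)
    bg = _markov_sequence(rng, L - island_len, gc_background)
    p_isl = np.array(
        [(1 - gc_island) / 2, gc_island / 2, gc_island / 2, (1 - gc_island) / 2]
    )
    island_codes = rng.choice(4, size=island_len, p=p_isl)
    margin = max(1, L // 20)
    pos = int(rng.integers(margin, L - island_len - margin))  # 0-based insert point
    codes = np.concatenate([bg[:pos], island_codes, bg[pos:]])
    island = GenomicInterval(contig_id, pos + 1, pos + island_len, "planted_island")
    gene_off = int(rng.integers(0, island_len - gene_len + 1))
    gene = GenomicInterval(
        contig_id,
        island.start + gene_off,
        island.start + gene_off + gene_len - 1,
        "planted_gene",
    )
    sim = GenomeSim(contig_id, _codes_to_str(codes), island, gene, seed)

    if fasta_path is not None:
        with open(fasta_path, "wt", encoding="utf-8") as fh:
            fh.write(f">{contig_id}\n")
            for i in range(0, L, 70):
                fh.write(sim.sequence[i : i + 70] + "\n")
    if gff_path is not None:
        with open(gff_path, "wt", encoding="utf-8") as fh:
            fh.write("##gff-version 3\n")
            fh.write(
                f"{contig_id}\thgtscreen_sim\tgene\t{gene.start}\t{gene.end}"
                f"\t.\t+\t.\tID=planted_gene\n"
            )
    if truth_path is not None:
        Path(truth_path).write_text(
            json.dumps(sim.truth, indent=1) + "\n", encoding="utf-8"
        )
    return sim


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------


@dataclass
class TreeSim:
    """A simulated support-annotated gene tree plus its label map."""

    newick: str
    label_map: dict[str, str]
    query_label: str
    placement: str  # "donor" | "recipient"
    seed: int


def _random_clade(
    rng: np.random.Generator,
    labels: list[str],
    support_range: tuple[float, float],
) -> str:
    """Random bifurcating clade over ``labels`` by successive joins."""
    lo, hi = support_range
    nodes = [f"{l}:{rng.uniform(0.05, 0.15):.4f}" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        sup = rng.uniform(lo, hi)
        bl = rng.uniform(0.05, 0.15)
        merged = f"({a},{b}){sup:.3f}:{bl:.4f}"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    return nodes[0]


def simulate_hgt_tree(
    n_donor: int = 8,
    n_recipient: int = 8,
    place_query: str = "donor",
    support_range: tuple[float, float] = (0.9, 1.0),
    seed: int = 0,
    query_label: str = "QUERY",
) -> TreeSim:
    """Two-clade gene tree with the query grafted into one clade.

    Donor leaves are plant-labelled (Eukaryota), recipient leaves bacterial;
    the query is a bacterial sequence placed inside the donor clade
    (``place_query="donor"``, the HGT pattern) or among the recipients
    (``"recipient"``, vertical descent).  Internal supports are drawn from
    ``support_range``; a long stem separates the two clades so midpoint
    rooting recovers the intended root.
    """
    if n_donor < 2 or n_recipient < 2:
        raise ValueError("need at least 2 leaves in each clade")
    if place_query not in ("donor", "recipient"):
        raise ValueError(f"place_query must be 'donor' or 'recipient', got {place_query!r}")
    rng = np.random.default_rng(seed)
    donors = [f"plant{j + 1:02d}" for j in range(n_donor)]
    recipients = [f"bact{j + 1:02d}" for j in range(n_recipient)]
    donor_leaves = donors + ([query_label] if place_query == "donor" else [])
    recip_leaves = recipients + ([query_label] if place_query == "recipient" else [])
    donor_clade = _random_clade(rng, donor_leaves, support_range)
    recip_clade = _random_clade(rng, recip_leaves, support_range)
    # strip the stem lengths the subclades carry and attach long stems
    newick = f"({donor_clade.rsplit(':', 1)[0]}:1.0,{recip_clade.rsplit(':', 1)[0]}:1.0);"
    label_map = {l: "Eukaryota" for l in donors}
    label_map.update({l: "Bacteria" for l in recipients})
    label_map[query_label] = "Bacteria"
    return TreeSim(newick, label_map, query_label, place_query, seed)


# --------------------------------------------------------------------------
# full input bundle
# --------------------------------------------------------------------------


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[rng.integers(0, len(_AA), size=length)])


def simulate_bundle(
    out_dir: Union[str, Path],
    seed: int = 0,
    n_background: int = 95,
    n_planted: int = 5,
    n_trees: int = 4,
    genome_length: int = 100_000,
    n_proteins: int = 4,
) -> dict:
    """Write a complete, internally consistent input set for the pipeline.

    Emits lineages (flat TSV), a hit table (blast tabular + taxid), a
    genome FASTA with a planted island and its gene GFF3, one tree per
    planted-style query (query grafted in the donor clade) plus one
    vertical-descent tree, protein FASTA + domain annotation TSV for the pI
    stage, and ``truth.json`` tying everything together.  Returns the path
    map; identical seeds give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    tax = simulate_taxonomy(50, 40, 5, 5, seed=seed, path=out / "lineages.tsv")
    hits = simulate_hit_tables(
        n_background,
        n_planted,
        taxonomy=tax,
        seed=seed,
        path=out / "hits.tsv",
        truth_path=out / "hits_truth.json",
    )
    genome = simulate_genome_with_island(
        L=genome_length,
        seed=seed,
        fasta_path=out / "genome.fasta",
        gff_path=out / "genes.gff3",
        truth_path=out / "genome_truth.json",
    )

    trees_dir = out / "trees"
    trees_dir.mkdir(exist_ok=True)
    planted_sorted = sorted(hits.planted_ids)
    tree_truth = {}
    label_map: dict[str, str] = {}
    for ti in range(n_trees):
        placement = "donor" if ti < n_trees - 1 else "recipient"
        qlabel = (
            planted_sorted[ti % len(planted_sorted)]
            if planted_sorted
            else f"q_extra{ti}"
        )
        tsim = simulate_hgt_tree(
            place_query=placement,
            seed=int(rng.integers(0, 2**31 - 1)),
            query_label=f"{qlabel}_t{ti}",
        )
        (trees_dir / f"tree{ti + 1:02d}.nwk").write_text(
            tsim.newick + "\n", encoding="utf-8"
        )
        # the label map covers database taxa only; query leaves stay
        # unmapped so the batch screen can infer them per tree
        label_map.update(
            {k: v for k, v in tsim.label_map.items() if k != tsim.query_label}
        )
        tree_truth[f"tree{ti + 1:02d}.nwk"] = {
            "query": tsim.query_label,
            "placement": placement,
        }
    with open(out / "leaf_domains.tsv", "wt", encoding="utf-8") as fh:
        for leaf, dom in sorted(label_map.items()):
            fh.write(f"{leaf}\t{dom}\n")

    prot_path = out / "proteins.fasta"
    ann_path = out / "domains.tsv"
    with open(prot_path, "wt", encoding="utf-8") as pf, open(
        ann_path, "wt", encoding="utf-8"
    ) as af:
        for pi_ in range(n_proteins):
            pid = f"prot{pi_ + 1:02d}"
            seq = _random_protein(rng, 250)
            pf.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                pf.write(seq[i : i + 60] + "\n")
            af.write(f"{pid}\tIPR007112\t31\t130\n")
            af.write(f"{pid}\tIPR007117\t151\t240\n")

    truth = {
        "seed": seed,
        "planted_queries": sorted(hits.planted_ids),
        "genome": genome.truth,
        "trees": tree_truth,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1) + "\n", encoding="utf-8")

    return {
        "lineages": out / "lineages.tsv",
        "hits": out / "hits.tsv",
        "hits_truth": out / "hits_truth.json",
        "genome": out / "genome.fasta",
        "genes": out / "genes.gff3",
        "genome_truth": out / "genome_truth.json",
        "trees_dir": trees_dir,
        "leaf_domains": out / "leaf_domains.tsv",
        "proteins": prot_path,
        "domains": ann_path,
        "truth": out / "truth.json",
    }
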