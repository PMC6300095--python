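"""Alien-hit-fraction screening of a proteome's homology hit tables.

The phyletic screen for inter-domain horizontal gene transfer works on the
output of a protein homology search (BLASTp-style tabular hits) run for
every protein of a focal proteome against a broad database.  For each query
the hits are classified alien/focal by superkingdom, and queries whose
alien fraction reaches the threshold tau (default: at least 80% of hits
non-focal) become HGT candidates for downstream tree-based confirmation.

Hits against the focal species itself (the query proteome is usually in the
database) are removed first via a configurable set of self taxon ids, and
at most ``max_hits`` best-by-bitscore hits are retained per query so that
extremely popular queries do not swamp the denominator.

The module also provides pairwise percent identity/similarity between two
protein sequences (global or local alignment, BLOSUM-class scoring), used
to compare candidate proteins across strains.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .taxonomy import Domain, DomainLabel, LineageTable, is_alien

__all__ = [
    "HomologyHit",
    "HitTable",
    "ScreenCounts",
    "QueryScreenResult",
    "HitTableParseError",
    "read_hit_table",
    "alien_fraction",
    "screen_proteome",
    "pairwise_identity",
    "IdentityResult",
    "write_screen_tsv",
    "write_screen_json",
    "write_hit_table",
]

logger = logging.getLogger(__name__)

#: 12 standard blast-tabular columns (``-outfmt 6`` order).
BLAST12_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
)


class HitTableParseError(Exception):
    """Raised for malformed hit-table rows; message names the line number."""


@dataclass(frozen=True)
class HomologyHit:
    """One homology-search hit (consumed, never produced, by this package)."""

    query_id: str
    subject_id: str
    taxon_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(
                f"percent_identity must be in [0,100], got {self.percent_identity}"
            )
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")
        if self.alignment_length < 1:
            raise ValueError(
                f"alignment_length must be >= 1, got {self.alignment_length}"
            )


@dataclass
class HitTable:
    """Hits grouped by query id, preserving input order of queries and hits."""

    queries: dict[str, list[HomologyHit]] = field(default_factory=dict)

    @property
    def n_queries(self) -> int:
        return len(self.queries)

    @property
    def n_hits(self) -> int:
        return sum(len(v) for v in self.queries.values())

    def add(self, hit: HomologyHit) -> None:
        self.queries.setdefault(hit.query_id, []).append(hit)

    def __iter__(self):
        return iter(self.queries.items())


def read_hit_table(
    path: Union[str, Path],
    taxid_col: int = 12,
) -> HitTable:
    """Read a blast-tabular file with an extra taxon-id column.

    The dialect is the standard 12-column tabular output plus one taxon-id
    column; ``taxid_col`` is the 0-based position of that column (default
    12, i.e. appended after the standard columns).  Comment lines starting
    with ``#`` are skipped.  Rows with the wrong column count raise
    :class:`HitTableParseError` naming the line.
    """
    path = Path(path)
    expected = max(13, taxid_col + 1)
    table = HitTable()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < expected:
                raise HitTableParseError(
                    f"{path}:{lineno}: expected >= {expected} columns "
                    f"(12 standard + taxon id at column {taxid_col}), "
                    f"got {len(fields)}"
                )
            std = [f for i, f in enumerate(fields) if i != taxid_col][:12]
            try:
                hit = HomologyHit(
                    query_id=std[0],
                    subject_id=std[1],
                    taxon_id=fields[taxid_col].strip(),
                    percent_identity=float(std[2]),
                    alignment_length=int(std[3]),
                    evalue=float(std[10]),
                    bitscore=float(std[11]),
                )
            except (ValueError, IndexError) as exc:
                raise HitTableParseError(f"{path}:{lineno}: {exc}") from exc
            table.add(hit)
    return table


def write_hit_table(
    table: HitTable, path: Union[str, Path], taxid_col: int = 12
) -> Path:
    """Write a 13-column blast-tabular(+taxid) file readable by
    :func:`read_hit_table`.  Fields this package does not model (mismatches,
    coordinates) are emitted as zeros."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(BLAST12_COLUMNS + ("taxon_id",)) + "\n")
        for query_id, hits in table:
            for h in hits:
                std = [
                    h.query_id,
                    h.subject_id,
                    f"{h.percent_identity:.1f}",
                    str(h.alignment_length),
                    "0",
                    "0",
                    "1",
                    str(h.alignment_length),
                    "1",
                    str(h.alignment_length),
                    f"{h.evalue:.3g}",
                    f"{h.bitscore:.1f}",
                ]
                if taxid_col < 12:
                    std.insert(taxid_col, h.taxon_id)
                else:
                    std.append(h.taxon_id)
                fh.write("\t".join(std) + "\n")
    return path


@dataclass(frozen=True)
class ScreenCounts:
    """Per-query hit bookkeeping for one alien-fraction computation."""

    n_total: int
    n_self: int
    n_alien: int
    n_focal: int
    n_excluded: int

    @property
    def n_usable(self) -> int:
        """Denominator of the alien fraction."""
        return self.n_alien + self.n_focal


def alien_fraction(
    hits: Sequence[HomologyHit],
    lineages: LineageTable,
    focal: Domain = Domain.BACTERIA,
    self_taxa: Iterable[str] = (),
    max_hits: Optional[int] = None,
    unknown_policy: str = "exclude",
) -> tuple[Optional[float], ScreenCounts]:
    """Alien fraction for one query's hits.

    Self-hits (``taxon_id`` in ``self_taxa``) are removed first; then at
    most ``max_hits`` best-by-bitscore hits are kept; each remaining hit is
    classified alien/focal/excluded by superkingdom and the fraction is
    ``alien / (alien + focal)``.  Returns ``(None, counts)`` when the
    denominator is zero.
    """
    if len({h.query_id for h in hits}) > 1:
        raise ValueError("alien_fraction expects hits from a single query")
    self_taxa = {str(t) for t in self_taxa}
    n_total = len(hits)
    kept = [h for h in hits if h.taxon_id not in self_taxa]
    n_self = n_total - len(kept)
    if max_hits is not None and len(kept) > max_hits:
        kept = sorted(kept, key=lambda h: -h.bitscore)[:max_hits]
    n_alien = n_focal = n_excluded = 0
    for h in kept:
        call = is_alien(h.taxon_id, focal, lineages, unknown_policy)
        if call == "alien":
            n_alien += 1
        elif call == "focal":
            n_focal += 1
        else:
            n_excluded += 1
    counts = ScreenCounts(n_total, n_self, n_alien, n_focal, n_excluded)
    if counts.n_usable == 0:
        return None, counts
    return n_alien / counts.n_usable, counts


@dataclass(frozen=True)
class QueryScreenResult:
    """Screening verdict for one query protein."""

    query_id: str
    n_hits_total: int
    n_self: int
    n_alien: int
    n_focal: int
    n_excluded: int
    alien_fraction: float  # NaN when status == "insufficient_hits"
    candidate: bool
    status: str  # "screened" | "insufficient_hits"


def screen_proteome(
    hit_table: HitTable,
    lineages: LineageTable,
    focal: Domain = Domain.BACTERIA,
    tau: float = 0.80,
    min_hits: int = 5,
    self_taxa: Iterable[str] = (),
    max_hits: Optional[int] = 250,
    unknown_policy: str = "exclude",
) -> list[QueryScreenResult]:
    """Screen every query; candidates have alien fraction >= tau (inclusive).

    A query whose usable-hit denominator (alien + focal, after self-hit
    removal and the bitscore cap) is below ``min_hits`` gets status
    ``insufficient_hits`` and is never a candidate.  Results are sorted by
    descending alien fraction, ties broken by query id; insufficient
    queries sort last.
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    if hit_table.n_queries == 0:
        logger.warning("empty hit table: nothing to screen")
        return []
    self_taxa = {str(t) for t in self_taxa}
    results = []
    for query_id, hits in hit_table:
        frac, c = alien_fraction(
            hits, lineages, focal, self_taxa, max_hits, unknown_policy
        )
        if frac is None or c.n_usable < min_hits:
            results.append(
                QueryScreenResult(
                    query_id,
                    c.n_total,
                    c.n_self,
                    c.n_alien,
                    c.n_focal,
                    c.n_excluded,
                    float("nan"),
                    False,
                    "insufficient_hits",
                )
            )
        else:
            results.append(
                QueryScreenResult(
                    query_id,
                    c.n_total,
                    c.n_self,
                    c.n_alien,
                    c.n_focal,
                    c.n_excluded,
                    frac,
                    frac >= tau,
                    "screened",
                )
            )
    results.sort(
        key=lambda r: (
            r.status != "screened",
            -(r.alien_fraction if not math.isnan(r.alien_fraction) else -1.0),
            r.query_id,
        )
    )
    return results


def write_screen_tsv(results: Sequence[QueryScreenResult], path: Union[str, Path]) -> Path:
    path = Path(path)
    cols = (
        "query_id",
        "n_hits_total",
        "n_self",
        "n_alien",
        "n_focal",
        "n_excluded",
        "alien_fraction",
        "candidate",
        "status",
    )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            frac = "NA" if math.isnan(r.alien_fraction) else f"{r.alien_fraction:.4f}"
            fh.write(
                f"{r.query_id}\t{r.n_hits_total}\t{r.n_self}\t{r.n_alien}\t"
                f"{r.n_focal}\t{r.n_excluded}\t{frac}\t"
                f"{str(r.candidate).lower()}\t{r.status}\n"
            )
    return path


def write_screen_json(results: Sequence[QueryScreenResult], path: Union[str, Path]) -> Path:
    path = Path(path)
    payload = []
    for r in results:
        d = asdict(r)
        if math.isnan(r.alien_fraction):
            d["alien_fraction"] = None
        payload.append(d)
    path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    return path


# --- pairwise identity / similarity ---------------------------------------

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZ*")


@dataclass(frozen=True)
class IdentityResult:
    """Percentages reported to one decimal, as in strain-comparison tables."""

    percent_identity: float
    percent_similarity: float
    percent_coverage: float
    n_columns: int
    score: float


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    mode: str = "global",
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> IdentityResult:
    """Percent identity/similarity/coverage from one pairwise alignment.

    Identity counts identical aligned residue pairs over all alignment
    columns (gap columns included in the denominator); similarity counts
    residue pairs with a positive substitution score; coverage is the
    aligned span on ``seq_a`` over its length.  Defaults: global alignment,
    BLOSUM62, gap open 10 / extend 0.5.
    """
    a, b = seq_a.strip().upper(), seq_b.strip().upper()
    if not a or not b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    for name, s in (("seq_a", a), ("seq_b", b)):
        bad = set(s) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"{name} contains non-protein letters: {sorted(bad)}")
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")

    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    subst = substitution_matrices.load(matrix)
    aligner.substitution_matrix = subst
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(a, b)[0]

    ga, gb = str(aln[0]), str(aln[1])
    assert len(ga) == len(gb)
    n_cols = n_ident = n_sim = 0
    for x, y in zip(ga, gb):
        if x == "-" and y == "-":
            continue
        n_cols += 1
        if x == "-" or y == "-":
            continue
        if x == y:
            n_ident += 1
        if subst[x, y] > 0:
            n_sim += 1
    blocks_a = aln.aligned[0]
    span = int(blocks_a[-1][1] - blocks_a[0][0]) if len(blocks_a) else 0
    return IdentityResult(
        percent_identity=round(100.0 * n_ident / n_cols, 1),
        percent_similarity=round(100.0 * n_sim / n_cols, 1),
        percent_coverage=round(100.0 * span / len(a), 1),
        n_columns=n_cols,
        score=float(aln.score),
    )
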