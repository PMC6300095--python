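"""Taxon lineages and the alien/focal classification.

The screening stage needs one piece of taxonomic information per homology
hit: does the hit's taxon belong to the focal clade (Bacteria, for a
bacterial query proteome) or to some other superkingdom?  Lineages are
loaded from flat files — either a two-file NCBI-style taxdump
(``nodes.dmp`` / ``names.dmp``) or a one-row-per-taxon TSV — into a
:class:`LineageTable`, and classification is a pure lookup against it.

Superkingdom is the classification rank; finer ranks (e.g. the kingdom
Viridiplantae) are carried along for reporting only.  A taxon missing from
the table, or present without a superkingdom-level rank, classifies as
``Unknown``; downstream code decides whether Unknown hits are excluded from
the alien-fraction denominator (the default) or counted on either side.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "Domain",
    "DomainLabel",
    "LineageTable",
    "TaxonomyError",
    "LineageParseError",
    "load_lineages",
    "classify_domain",
    "is_alien",
    "UNKNOWN_POLICIES",
]

#: Ranks accepted as superkingdom-level (NCBI renamed the rank to "domain").
SUPERKINGDOM_RANKS = frozenset({"superkingdom", "domain"})

KINGDOM_RANK = "kingdom"


class TaxonomyError(Exception):
    """Base error for taxonomy loading/classification."""


class LineageParseError(TaxonomyError):
    """A lineage file could not be parsed; message names the offending line."""


class Domain(str, enum.Enum):
    """Superkingdom-level labels used for the alien/focal call."""

    BACTERIA = "Bacteria"
    ARCHAEA = "Archaea"
    EUKARYOTA = "Eukaryota"
    VIRUSES = "Viruses"
    UNKNOWN = "Unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_DOMAIN_BY_NAME = {d.value.lower(): d for d in Domain}
# common synonyms seen in dumps
_DOMAIN_BY_NAME.update(
    {
        "eukarya": Domain.EUKARYOTA,
        "virus": Domain.VIRUSES,
    }
)


@dataclass(frozen=True)
class DomainLabel:
    """A superkingdom call plus an optional kingdom tag for reporting.

    ``kingdom`` (e.g. ``"Viridiplantae"``) never affects the alien/focal
    decision; equality for screening purposes is on ``domain`` alone.
    """

    domain: Domain
    kingdom: str | None = None

    @property
    def is_unknown(self) -> bool:
        return self.domain is Domain.UNKNOWN


Lineage = Sequence[tuple[str, str]]


@dataclass
class LineageTable:
    """Mapping of taxon id -> ordered (rank, name) lineage, root first."""

    entries: dict[str, tuple[tuple[str, str], ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, taxon_id: object) -> bool:
        return str(taxon_id) in self.entries

    def lineage(self, taxon_id: Union[str, int]) -> tuple[tuple[str, str], ...]:
        """Return the lineage for ``taxon_id``; a defined miss raises KeyError."""
        key = str(taxon_id)
        if key not in self.entries:
            raise KeyError(f"taxon id {key!r} not in lineage table")
        return self.entries[key]

    def add(self, taxon_id: Union[str, int], lineage: Lineage) -> None:
        key = str(taxon_id)
        if key in self.entries:
            raise TaxonomyError(f"duplicate taxon id {key!r}")
        if not lineage:
            raise TaxonomyError(f"empty lineage for taxon id {key!r}")
        self.entries[key] = tuple((str(r), str(n)) for r, n in lineage)


def _parse_flat_tsv(path: Path) -> LineageTable:
    table = LineageTable()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise LineageParseError(
                    f"{path}:{lineno}: expected taxon id plus at least one "
                    f"rank:name pair, got {len(fields)} column(s)"
                )
            taxon_id = fields[0].strip()
            if not taxon_id:
                raise LineageParseError(f"{path}:{lineno}: empty taxon id")
            lineage = []
            for col, pair in enumerate(fields[1:], start=2):
                if not pair.strip():
                    continue
                rank, sep, name = pair.partition(":")
                if not sep or not rank.strip() or not name.strip():
                    raise LineageParseError(
                        f"{path}:{lineno}: column {col}: expected 'rank:name', "
                        f"got {pair!r}"
                    )
                lineage.append((rank.strip(), name.strip()))
            if not lineage:
                raise LineageParseError(f"{path}:{lineno}: empty lineage")
            try:
                table.add(taxon_id, lineage)
            except TaxonomyError as exc:
                raise LineageParseError(f"{path}:{lineno}: {exc}") from exc
    return table


def _split_dmp(line: str) -> list[str]:
    # taxdump rows are "field\t|\tfield\t|\t...\t|"
    return [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]


def _parse_taxdump(nodes_path: Path, names_path: Path) -> LineageTable:
    parents: dict[str, str] = {}
    ranks: dict[str, str] = {}
    with open(nodes_path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = _split_dmp(raw)
            if len(fields) < 3:
                raise LineageParseError(
                    f"{nodes_path}:{lineno}: expected >=3 '|'-separated fields"
                )
            taxid, parent, rank = fields[0], fields[1], fields[2]
            if taxid in parents:
                raise LineageParseError(f"{nodes_path}:{lineno}: duplicate taxid {taxid}")
            parents[taxid] = parent
            ranks[taxid] = rank

    names: dict[str, str] = {}
    with open(names_path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = _split_dmp(raw)
            if len(fields) < 2:
                raise LineageParseError(
                    f"{names_path}:{lineno}: expected >=2 '|'-separated fields"
                )
            taxid, name = fields[0], fields[1]
            name_class = fields[3] if len(fields) > 3 else "scientific name"
            if name_class == "scientific name" or taxid not in names:
                names[taxid] = name

    table = LineageTable()
    for taxid in parents:
        # follow parent pointers to the root, keep ranked nodes, root first
        chain: list[str] = []
        node = taxid
        seen = set()
        while node not in seen:
            seen.add(node)
            chain.append(node)
            parent = parents.get(node)
            if parent is None or parent == node:
                break
            node = parent
        lineage = [
            (ranks[n], names.get(n, n))
            for n in reversed(chain)
            if ranks.get(n, "no rank") != "no rank"
        ]
        if not lineage:
            # root-only nodes (e.g. the taxdump root itself) are not taxa
            # callers can classify; keep them out of the table.
            continue
        table.add(taxid, lineage)
    return table


def load_lineages(
    path: Union[str, Path, tuple],
    format: str = "flat_tsv",
) -> LineageTable:
    """Load a :class:`LineageTable` from disk.

    Parameters
    ----------
    path
        For ``flat_tsv``: the TSV file (one row per taxon:
        ``taxon_id<TAB>rank:name<TAB>rank:name...``, root first).
        For ``taxdump_pair``: either a directory containing ``nodes.dmp``
        and ``names.dmp`` or a ``(nodes_path, names_path)`` tuple.
    format
        ``"flat_tsv"`` or ``"taxdump_pair"``.
    """
    if format == "flat_tsv":
        p = Path(path)
        if not p.is_file():
            raise FileNotFoundError(f"lineage table not found: {p}")
        return _parse_flat_tsv(p)
    if format == "taxdump_pair":
        if isinstance(path, (tuple, list)):
            nodes, names = Path(path[0]), Path(path[1])
        else:
            d = Path(path)
            nodes, names = d / "nodes.dmp", d / "names.dmp"
        for p in (nodes, names):
            if not p.is_file():
                raise FileNotFoundError(f"taxdump file not found: {p}")
        return _parse_taxdump(nodes, names)
    raise ValueError(f"unknown lineage format {format!r}")


def classify_domain(taxon_id: Union[str, int], table: LineageTable) -> DomainLabel:
    """Superkingdom classification of a taxon; missing taxa are Unknown.

    Pure function of the table: repeated calls agree.
    """
    try:
        lineage = table.lineage(taxon_id)
    except KeyError:
        return DomainLabel(Domain.UNKNOWN)
    domain = Domain.UNKNOWN
    kingdom = None
    for rank, name in lineage:
        rl = rank.lower()
        if rl in SUPERKINGDOM_RANKS and domain is Domain.UNKNOWN:
            domain = _DOMAIN_BY_NAME.get(name.lower(), Domain.UNKNOWN)
        elif rl == KINGDOM_RANK and kingdom is None:
            kingdom = name
    return DomainLabel(domain, kingdom)


#: How hits whose taxon classifies as Unknown enter the alien fraction.
UNKNOWN_POLICIES = ("exclude", "count_as_alien", "count_as_focal")


def is_alien(
    taxon_id: Union[str, int],
    focal: Union[Domain, DomainLabel],
    table: LineageTable,
    unknown_policy: str = "exclude",
) -> str:
    """Tri-state alien/focal/excluded call for one taxon.

    ``alien`` iff the taxon's superkingdom differs from ``focal`` and is not
    Unknown; Unknown taxa follow ``unknown_policy`` (default: excluded from
    both classes, hence from the alien-fraction denominator).
    """
    focal_domain = focal.domain if isinstance(focal, DomainLabel) else focal
    if not isinstance(focal_domain, Domain):
        focal_domain = Domain(str(focal_domain))
    if focal_domain is Domain.UNKNOWN:
        raise ValueError("focal domain must not be Unknown")
    if unknown_policy not in UNKNOWN_POLICIES:
        raise ValueError(
            f"unknown_policy must be one of {UNKNOWN_POLICIES}, got {unknown_policy!r}"
        )
    label = classify_domain(taxon_id, table)
    if label.is_unknown:
        return {
            "exclude": "excluded",
            "count_as_alien": "alien",
            "count_as_focal": "focal",
        }[unknown_policy]
    return "focal" if label.domain is focal_domain else "alien"


def write_lineage_tsv(table: LineageTable, path: Union[str, Path]) -> Path:
    """Write a table in the flat-TSV dialect that :func:`load_lineages` reads."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        for taxon_id, lineage in table.entries.items():
            pairs = "\t".join(f"{rank}:{name}" for rank, name in lineage)
            fh.write(f"{taxon_id}\t{pairs}\n")
    return path
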