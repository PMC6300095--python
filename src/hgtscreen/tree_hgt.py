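"""Automated tree-topology test for an HGT pattern.

Tree-based confirmation of a horizontally transferred gene asks whether the
query protein's leaf is nested inside a well-supported clade of donor
(alien-superkingdom) sequences rather than among its own relatives.  Gene
trees are consumed as support-annotated Newick (SH-like supports in [0,1]
or bootstrap percentages, auto-detected and normalized); the judgement that
is usually made by eye is formalized here:

1. root the tree (explicit outgroup if given, else midpoint when branch
   lengths are available, else the tree is used as written);
2. find the smallest clade containing the query with at least ``m_min``
   non-query leaves;
3. call ``hgt_consistent`` iff the fraction of those leaves that are alien
   (superkingdom differing from the focal one) reaches ``p_min`` AND the
   clade's branch support reaches ``s_min``; a pure-alien clade with weak
   or missing support is ``unsupported``; anything else ``not_consistent``.

Supports are treated as properties of bipartitions, so rooting operations
cannot silently reattach them to the wrong node.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import dendropy
import pandas as pd

from .taxonomy import Domain, DomainLabel

__all__ = [
    "TaxonLabeledTree",
    "HgtCall",
    "NewickParseError",
    "read_newick",
    "read_label_map",
    "hgt_topology_test",
    "batch_tree_screen",
]

logger = logging.getLogger(__name__)

VERDICTS = ("hgt_consistent", "not_consistent", "unsupported", "query_absent")


class NewickParseError(Exception):
    """Raised when a Newick file cannot be parsed or supports are malformed."""


@dataclass
class TaxonLabeledTree:
    """A parsed gene tree with supports normalized to [0, 1].

    ``supports`` maps the frozenset of leaf labels below an internal node
    (as the tree was read) to that node's support; missing supports are
    simply absent from the map, never recorded as zero.
    """

    tree: dendropy.Tree
    supports: dict[frozenset, float]
    has_lengths: bool
    source: Optional[str] = None

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(
            lf.taxon.label for lf in self.tree.leaf_node_iter() if lf.taxon is not None
        )


def _normalize_supports(raw: dict[frozenset, float], source: str) -> dict[frozenset, float]:
    if not raw:
        return {}
    vals = list(raw.values())
    if max(vals) > 100.0:
        raise NewickParseError(f"{source}: support value {max(vals)} exceeds 100")
    if max(vals) > 1.5:  # percent scale
        if any(0.0 < v < 1.0 for v in vals):
            raise NewickParseError(
                f"{source}: mixed support scales (values both in (0,1) and above 1.5)"
            )
        return {k: v / 100.0 for k, v in raw.items()}
    return dict(raw)


def read_newick(source: Union[str, Path], is_string: bool = False) -> TaxonLabeledTree:
    """Parse a Newick tree; numeric internal-node labels become supports.

    Supports on a percent scale (max value > 1.5) are divided by 100;
    files mixing the two scales are rejected.  Duplicate leaf labels are an
    error.  ``is_string`` reads ``source`` as Newick text instead of a path.
    """
    if is_string:
        text, name = str(source), "<string>"
    else:
        p = Path(source)
        text, name = p.read_text(encoding="utf-8"), str(p)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"{name}: {exc}") from exc

    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"{name}: duplicate leaf labels {dupes}")

    raw: dict[frozenset, float] = {}
    for node in tree.preorder_internal_node_iter():
        if node.label is None:
            continue
        try:
            val = float(node.label)
        except ValueError:
            continue  # non-numeric internal labels are names, not supports
        leafset = frozenset(
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
        )
        raw[leafset] = val
    supports = _normalize_supports(raw, name)
    has_lengths = any(
        e.length is not None and e.length > 0 for e in tree.preorder_edge_iter()
    )
    return TaxonLabeledTree(tree, supports, has_lengths, name)


def read_label_map(path: Union[str, Path]) -> dict[str, DomainLabel]:
    """Two-column TSV ``leaf_label<TAB>superkingdom`` -> DomainLabel map."""
    mapping: dict[str, DomainLabel] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            mapping[fields[0]] = DomainLabel(Domain(fields[1].strip()))
    return mapping


@dataclass(frozen=True)
class HgtCall:
    """Outcome of the topology test for one query in one tree."""

    query_label: str
    verdict: str
    supporting_clade: tuple[str, ...] = ()
    clade_support: Optional[float] = None
    alien_purity: float = float("nan")

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def _coerce_domain(value: Union[Domain, DomainLabel, str]) -> Domain:
    if isinstance(value, DomainLabel):
        return value.domain
    if isinstance(value, Domain):
        return value
    return Domain(str(value))


def _lookup_support(
    supports: Mapping[frozenset, float],
    clade: frozenset,
    all_leaves: frozenset,
) -> Optional[float]:
    # a bipartition may be recorded from either side of its edge
    if clade in supports:
        return supports[clade]
    comp = all_leaves - clade
    return supports.get(comp)


def hgt_topology_test(
    ttree: TaxonLabeledTree,
    query_label: str,
    label_map: Mapping[str, Union[Domain, DomainLabel, str]],
    focal: Union[Domain, str] = Domain.BACTERIA,
    s_min: float = 0.8,
    p_min: float = 1.0,
    m_min: int = 2,
    outgroup: Optional[Sequence[str]] = None,
) -> HgtCall:
    """Decide whether ``query_label`` sits inside a supported alien clade.

    ``label_map`` maps every non-query leaf label to a superkingdom; leaves
    absent from the map raise ``KeyError``.  See the module docstring for
    the decision rule.
    """
    focal_domain = _coerce_domain(focal)
    if not (0.0 <= s_min <= 1.0 and 0.0 <= p_min <= 1.0):
        raise ValueError("s_min and p_min must lie in [0, 1]")
    if m_min < 1:
        raise ValueError("m_min must be >= 1")

    work = copy.deepcopy(ttree.tree)
    leaf_labels = frozenset(
        lf.taxon.label for lf in work.leaf_node_iter() if lf.taxon is not None
    )
    if query_label not in leaf_labels:
        return HgtCall(query_label, "query_absent")

    missing = [
        l for l in leaf_labels if l != query_label and l not in label_map
    ]
    if missing:
        raise KeyError(f"leaves missing from the label map: {sorted(missing)[:5]}")

    if outgroup:
        og = [l for l in outgroup if l in leaf_labels and l != query_label]
        if og:
            taxa = [t for t in work.taxon_namespace if t.label in og]
            work.is_rooted = True
            mrca = work.mrca(taxa=taxa)
            if mrca is not work.seed_node:
                work.reroot_at_edge(mrca.edge, update_bipartitions=False)
    elif ttree.has_lengths:
        try:
            work.reroot_at_midpoint(update_bipartitions=False)
        except Exception:  # zero-length degenerate trees: keep as-read rooting
            logger.debug("midpoint rooting failed; using tree as read")

    query_leaf = next(
        lf
        for lf in work.leaf_node_iter()
        if lf.taxon is not None and lf.taxon.label == query_label
    )

    node = query_leaf.parent_node
    chosen = None
    while node is not None:
        clade = frozenset(
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
        )
        if len(clade - {query_label}) >= m_min:
            chosen = (node, clade)
            break
        node = node.parent_node
    if chosen is None:  # tree too small: fall back to all leaves
        chosen = (work.seed_node, leaf_labels)
    node, clade = chosen

    others = sorted(clade - {query_label})
    n_alien = sum(
        1
        for l in others
        if _coerce_domain(label_map[l]) not in (focal_domain, Domain.UNKNOWN)
    )
    purity = n_alien / len(others)
    support = None
    if node is not work.seed_node:
        support = _lookup_support(ttree.supports, clade, leaf_labels)

    if purity >= p_min:
        if support is not None and support >= s_min:
            verdict = "hgt_consistent"
        else:
            verdict = "unsupported"
    else:
        verdict = "not_consistent"
    return HgtCall(query_label, verdict, tuple(others), support, purity)


def batch_tree_screen(
    trees_dir: Union[str, Path],
    label_map: Mapping[str, Union[Domain, DomainLabel, str]],
    query_label: Optional[str] = None,
    focal: Union[Domain, str] = Domain.BACTERIA,
    s_min: float = 0.8,
    p_min: float = 1.0,
    m_min: int = 2,
    outgroup: Optional[Sequence[str]] = None,
    pattern: str = "*.nwk",
) -> pd.DataFrame:
    """Run the topology test over a directory of Newick files.

    When ``query_label`` is None the query is inferred per tree as the
    unique leaf whose mapped superkingdom equals ``focal`` (the usual
    one-candidate-per-tree layout).  Unreadable or ambiguous trees are
    reported as rows with verdict ``read_error``, never raised.
    """
    trees_dir = Path(trees_dir)
    focal_domain = _coerce_domain(focal)
    files = sorted(trees_dir.glob(pattern)) or sorted(trees_dir.glob("*.newick"))
    if not files:
        logger.warning("no tree files found in %s", trees_dir)
    rows = []
    for f in files:
        try:
            ttree = read_newick(f)
            q = query_label
            if q is None:
                # the label map normally covers the database taxa, not the
                # candidate: a single unmapped leaf is the query.  Otherwise
                # fall back to a unique focal-domain leaf.
                unmapped = [l for l in ttree.leaf_labels if l not in label_map]
                focal_leaves = [
                    l
                    for l in ttree.leaf_labels
                    if l in label_map and _coerce_domain(label_map[l]) is focal_domain
                ]
                if len(unmapped) == 1:
                    q = unmapped[0]
                elif not unmapped and len(focal_leaves) == 1:
                    q = focal_leaves[0]
                else:
                    raise ValueError(
                        f"cannot infer query leaf ({len(unmapped)} unmapped, "
                        f"{len(focal_leaves)} focal leaves); pass query_label"
                    )
            lm = dict(label_map)
            lm.setdefault(q, DomainLabel(focal_domain))
            call = hgt_topology_test(
                ttree, q, lm, focal_domain, s_min, p_min, m_min, outgroup
            )
            rows.append(
                {
                    "tree": f.name,
                    "query": q,
                    "verdict": call.verdict,
                    "clade_support": call.clade_support,
                    "alien_purity": call.alien_purity,
                    "clade_size": len(call.supporting_clade),
                    "error": "",
                }
            )
        except Exception as exc:
            logger.warning("failed to screen %s: %s", f, exc)
            rows.append(
                {
                    "tree": f.name,
                    "query": query_label or "",
                    "verdict": "read_error",
                    "clade_support": math.nan,
                    "alien_purity": math.nan,
                    "clade_size": 0,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "tree",
            "query",
            "verdict",
            "clade_support",
            "alien_purity",
            "clade_size",
            "error",
        ],
    )
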