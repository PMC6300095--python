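"""Isoelectric points of annotated protein domain segments.

The isoelectric point (pI) of a polypeptide is the pH at which its net
charge vanishes.  Net charge is modelled by the Henderson–Hasselbalch sum
over ionizable groups

    Q(pH) = sum_pos n_g / (1 + 10^(pH - pKa_g))
          - sum_neg n_g / (1 + 10^(pKa_g - pH))

with positive groups {N-terminus, His, Lys, Arg} and negative groups
{C-terminus, Cys, Asp, Glu, Tyr}.  Q is monotone non-increasing in pH, so
the pI is the unique root on [0, 14], found by bisection.

Because published pI values rarely state which pKa constants were used,
several presets ship here (Bjellqvist-style, IPC-protein-style, EMBOSS)
and per-preset tables can be compared side by side.  Domain segments are
internal fragments of a protein; the termini are still included in the
charge model by default — a single documented convention, flagged in the
output — since expansin domain pI tables are comparative, not absolute.

Expansins carry two domains: the N-terminal DPBB domain (signature
IPR007112, a non-enzymatic relative of family-45 glycosyl hydrolases) and
the C-terminal cellulose-binding-like domain CBD (IPR007117).  Their pI
contrast — e.g. an unusually acidic CBD — is the screening readout here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.optimize import bisect

__all__ = [
    "PkaSet",
    "DomainSegment",
    "UndefinedPIError",
    "PKA_SETS",
    "BJELLQVIST",
    "IPC_PROTEIN",
    "EMBOSS",
    "SIGNATURE_DOMAINS",
    "net_charge",
    "isoelectric_point",
    "domain_pi_table",
    "read_domain_annotations",
    "pi_preset_comparison",
]

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: InterPro signature -> short domain name used in reports.
SIGNATURE_DOMAINS = {"IPR007112": "DPBB", "IPR007117": "CBD"}


class UndefinedPIError(ValueError):
    """The net-charge curve has no zero on [0, 14] for this sequence."""


@dataclass(frozen=True)
class PkaSet:
    """Named pKa constants for the ionizable groups of a protein.

    ``positive`` maps side chains {H, K, R} and ``negative`` maps
    {C, D, E, Y}; the termini have their own constants.  All values are in
    pH units and must lie in (0, 14).
    """

    name: str
    positive: Mapping[str, float]
    negative: Mapping[str, float]
    n_term: float
    c_term: float
    #: residue-specific terminal pKa (Bjellqvist's tables adjust the termini
    #: by the identity of the first/last residue); empty for most presets.
    n_term_overrides: Mapping[str, float] = None  # type: ignore[assignment]
    c_term_overrides: Mapping[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_term_overrides is None:
            object.__setattr__(self, "n_term_overrides", {})
        if self.c_term_overrides is None:
            object.__setattr__(self, "c_term_overrides", {})
        for v in (
            *self.positive.values(),
            *self.negative.values(),
            *self.n_term_overrides.values(),
            *self.c_term_overrides.values(),
            self.n_term,
            self.c_term,
        ):
            if not (0.0 < v < 14.0):
                raise ValueError(f"pKa {v} outside (0, 14) in set {self.name!r}")

    def n_term_pka(self, first_residue: str) -> float:
        return self.n_term_overrides.get(first_residue, self.n_term)

    def c_term_pka(self, last_residue: str) -> float:
        return self.c_term_overrides.get(last_residue, self.c_term)


#: Bjellqvist constants (the common default of pI calculators), including
#: the residue-specific terminal adjustments of the published tables.
BJELLQVIST = PkaSet(
    "bjellqvist",
    positive={"K": 10.0, "R": 12.0, "H": 5.98},
    negative={"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    n_term=7.5,
    c_term=3.55,
    n_term_overrides={
        "A": 7.59,
        "M": 7.0,
        "S": 6.93,
        "P": 8.36,
        "T": 6.82,
        "V": 7.44,
        "E": 7.7,
    },
    c_term_overrides={"D": 4.55, "E": 4.75},
)

#: IPC protein-optimized constants.
IPC_PROTEIN = PkaSet(
    "ipc_protein",
    positive={"K": 9.052, "R": 11.84, "H": 5.637},
    negative={"D": 3.872, "E": 4.412, "C": 7.555, "Y": 10.85},
    n_term=9.094,
    c_term=2.869,
)

#: EMBOSS iep defaults.
EMBOSS = PkaSet(
    "emboss",
    positive={"K": 10.8, "R": 12.5, "H": 6.5},
    negative={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    n_term=8.6,
    c_term=3.6,
)

PKA_SETS: dict[str, PkaSet] = {s.name: s for s in (BJELLQVIST, IPC_PROTEIN, EMBOSS)}


@dataclass(frozen=True)
class DomainSegment:
    """A protein subsequence with 1-based inclusive residue coordinates."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"require 1 <= start <= end, got {self.start}..{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.protein_id}/{self.domain_name}: sequence length "
                f"{len(self.sequence)} != {self.end - self.start + 1} "
                f"({self.start}..{self.end})"
            )
        bad = set(self.sequence.upper()) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"{self.protein_id}/{self.domain_name}: non-protein letters {sorted(bad)}"
            )


def _sequence_of(segment: Union[str, DomainSegment]) -> str:
    seq = segment.sequence if isinstance(segment, DomainSegment) else segment
    seq = seq.upper()
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"non-protein letters in sequence: {sorted(bad)}")
    return seq


def net_charge(
    segment: Union[str, DomainSegment],
    pH: Union[float, np.ndarray],
    pka_set: PkaSet = BJELLQVIST,
    include_termini: bool = True,
):
    """Net charge Q(pH) in elementary charges; accepts scalar or array pH.

    X residues contribute no charge.  Vectorized over pH for grid oracles.
    """
    seq = _sequence_of(segment)
    pH = np.asarray(pH, dtype=float)
    if np.any(pH < 0) or np.any(pH > 14):
        raise ValueError("pH must lie in [0, 14]")
    q = np.zeros_like(pH, dtype=float)
    for res, pka in pka_set.positive.items():
        n = seq.count(res)
        if n:
            q += n / (1.0 + 10.0 ** (pH - pka))
    for res, pka in pka_set.negative.items():
        n = seq.count(res)
        if n:
            q -= n / (1.0 + 10.0 ** (pka - pH))
    if include_termini:
        q += 1.0 / (1.0 + 10.0 ** (pH - pka_set.n_term_pka(seq[0])))
        q -= 1.0 / (1.0 + 10.0 ** (pka_set.c_term_pka(seq[-1]) - pH))
    return float(q) if q.ndim == 0 else q


def _has_both_signs(seq: str, pka_set: PkaSet, include_termini: bool) -> bool:
    pos = include_termini or any(seq.count(r) for r in pka_set.positive)
    neg = include_termini or any(seq.count(r) for r in pka_set.negative)
    return pos and neg


def isoelectric_point(
    segment: Union[str, DomainSegment],
    pka_set: PkaSet = BJELLQVIST,
    include_termini: bool = True,
    tol: float = 1e-4,
) -> float:
    """pI as the bisection root of Q(pH) = 0 on [0, 14], to |dpH| <= tol.

    Raises :class:`UndefinedPIError` when the sequence has no charged group
    of one sign (Q never crosses zero).
    """
    seq = _sequence_of(segment)
    if not _has_both_signs(seq, pka_set, include_termini):
        raise UndefinedPIError(
            "pI undefined: sequence lacks a charged group of each sign"
        )
    f = lambda x: net_charge(seq, x, pka_set, include_termini)
    q0, q14 = f(0.0), f(14.0)
    if q0 == 0.0:
        return 0.0
    if q14 == 0.0:
        return 14.0
    if not (q0 > 0.0 > q14):
        raise UndefinedPIError(
            f"pI undefined: Q(0)={q0:.3g}, Q(14)={q14:.3g} do not bracket zero"
        )
    return float(bisect(f, 0.0, 14.0, xtol=tol))


def read_domain_annotations(
    path: Union[str, Path],
    signature_domains: Mapping[str, str] = SIGNATURE_DOMAINS,
) -> list[tuple[str, str, str, int, int]]:
    """Read domain annotations from an InterProScan-style TSV.

    Accepts either the full InterProScan layout (>= 8 tab-separated
    columns: protein accession, md5, length, analysis, signature accession,
    signature description, start, stop, ...) or a minimal 4-column layout
    (protein id, signature accession, start, end).  Returns rows
    ``(protein_id, domain_name, signature, start, end)`` in input order,
    with signatures mapped to short domain names where known.
    """
    path = Path(path)
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) >= 8:
                pid, sig, start, end = f[0], f[4], f[6], f[7]
            elif len(f) == 4:
                pid, sig, start, end = f
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 or >=8 columns, got {len(f)}"
                )
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            domain = signature_domains.get(sig, "other")
            rows.append((pid.strip(), domain, sig.strip(), s, e))
    return rows


def _load_fasta(fasta: Union[str, Path, Mapping[str, str]]) -> dict[str, str]:
    if isinstance(fasta, Mapping):
        return {k: str(v) for k, v in fasta.items()}
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(Path(fasta)), "fasta")
    }


def domain_pi_table(
    fasta: Union[str, Path, Mapping[str, str]],
    annotations: Union[str, Path, Sequence[tuple]],
    pka_set: Union[str, PkaSet] = BJELLQVIST,
    include_termini: bool = True,
) -> pd.DataFrame:
    """pI of every annotated domain segment, one row per (protein, domain).

    ``fasta`` is a FASTA path or an id->sequence mapping; ``annotations``
    is an InterProScan-style TSV path or pre-parsed rows from
    :func:`read_domain_annotations`.  Rows keep input order; pI is reported
    to two decimals.  An annotation naming a protein missing from the FASTA
    or exceeding its length raises ``ValueError`` naming the annotation;
    segments whose pI is undefined get a NaN pI and an explanatory note.
    """
    if isinstance(pka_set, str):
        pka_set = PKA_SETS[pka_set]
    seqs = _load_fasta(fasta)
    if isinstance(annotations, (str, Path)):
        annotations = read_domain_annotations(annotations)
    rows = []
    for pid, domain, sig, start, end in annotations:
        if pid not in seqs:
            raise ValueError(f"annotation {pid}/{sig}: protein not in FASTA")
        seq = seqs[pid]
        if end > len(seq):
            raise ValueError(
                f"annotation {pid}/{sig} {start}..{end}: end exceeds protein "
                f"length {len(seq)}"
            )
        segment = DomainSegment(pid, domain, start, end, seq[start - 1 : end])
        note = ""
        try:
            pi = round(isoelectric_point(segment, pka_set, include_termini), 2)
        except UndefinedPIError as exc:
            pi, note = float("nan"), str(exc)
        rows.append(
            {
                "protein_id": pid,
                "domain": domain,
                "signature": sig,
                "start": start,
                "end": end,
                "length": segment.end - segment.start + 1,
                "pI": pi,
                "pka_set": pka_set.name,
                "termini_included": include_termini,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def pi_preset_comparison(
    fasta: Union[str, Path, Mapping[str, str]],
    annotations: Union[str, Path, Sequence[tuple]],
    pka_sets: Iterable[Union[str, PkaSet]] = ("bjellqvist", "ipc_protein"),
    include_termini: bool = True,
) -> pd.DataFrame:
    """Side-by-side pI per pKa preset, plus the spread across presets.

    Published pI tables rarely state their constants; this view shows how
    much the choice of preset moves each value.
    """
    sets = [PKA_SETS[s] if isinstance(s, str) else s for s in pka_sets]
    if len(sets) < 2:
        raise ValueError("need at least two pKa sets to compare")
    base = None
    for s in sets:
        tab = domain_pi_table(fasta, annotations, s, include_termini)
        col = tab[["protein_id", "domain", "signature", "start", "end", "pI"]].rename(
            columns={"pI": f"pI_{s.name}"}
        )
        base = col if base is None else base.merge(
            col, on=["protein_id", "domain", "signature", "start", "end"]
        )
    pi_cols = [c for c in base.columns if c.startswith("pI_")]
    base["pI_spread"] = base[pi_cols].max(axis=1) - base[pi_cols].min(axis=1)
    return base
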