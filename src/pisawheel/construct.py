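"""Construct representation for the syndecan-4 ecto/TM/cyto peptide (Syd4-eTC).

Holds the one-letter sequence, the mapping from construct position to
full-length syndecan-4 residue numbering, named domain spans, and
sequence-motif utilities (GXXXG scan for the dimerization motif).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

__all__ = [
    "AA_CODES",
    "AA_THREE_LETTER",
    "SYD4_ETC_SEQUENCE",
    "DEFAULT_FIRST_FULL_NUMBER",
    "DEFAULT_DOMAIN_SPANS",
    "Construct",
    "make_construct",
    "construct_from_fasta",
    "count_residue",
    "map_residue",
    "find_gxxxg",
]

AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")

AA_THREE_LETTER = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}

#: 57-residue syndecan-4 construct: short ecto stub, full TM helix, full
#: cytoplasmic domain (C1 / V / C2).
SYD4_ETC_SEQUENCE = "ERTEVLAALIVGGVVGILFAVFLILLLVYRIKKKDEGSYDLGKKPIYKKAPTNEFYA"

#: Full-length syndecan-4 number of construct position 1.  Chosen so the
#: unique cytoplasmic-domain serine (construct position 38) maps to Ser179,
#: the PKC-regulatory phosphorylation site.  Under this offset the V-domain
#: tyrosine at construct position 47 maps to Tyr188; the alternative
#: convention (Tyr187, offset 141) is selectable via the constructor — the
#: two published anchors differ by one and we do not adjudicate.
DEFAULT_FIRST_FULL_NUMBER = 142

#: Domain boundaries in construct (1-based, inclusive) coordinates.  The
#: ecto stub is the four N-terminal residues, the TM helix spans the
#: 25-residue hydrophobic stretch, and the cytoplasmic domain divides into
#: conserved-1, variable, and conserved-2 subregions.
DEFAULT_DOMAIN_SPANS: Mapping[str, tuple[int, int]] = {
    "ecto": (1, 4),
    "tm": (5, 29),
    "cyto": (30, 57),
    "c1": (30, 39),
    "v": (40, 52),
    "c2": (53, 57),
}

# domain tiers that must not overlap internally
_TIERS = (("ecto", "tm", "cyto"), ("c1", "v", "c2"))


@dataclass(frozen=True)
class Construct:
    """A validated peptide construct with full-length numbering.

    Attributes
    ----------
    sequence : str
        One-letter amino-acid codes, no whitespace.
    first_full_number : int
        Full-length residue number of construct position 1.
    domain_spans : dict
        Named 1-based inclusive spans over construct positions.
    """

    sequence: str
    first_full_number: int = DEFAULT_FIRST_FULL_NUMBER
    domain_spans: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_SPANS)
    )

    def __len__(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in AA_CODES:
                raise ValueError(
                    f"invalid amino-acid code {aa!r} at position {i}"
                )
        n = len(self.sequence)
        for name, (lo, hi) in self.domain_spans.items():
            if not (1 <= lo <= hi <= n):
                raise ValueError(
                    f"domain span {name!r} = ({lo}, {hi}) outside [1, {n}]"
                )
        for tier in _TIERS:
            spans = sorted(
                self.domain_spans[name] for name in tier
                if name in self.domain_spans
            )
            for (_, hi_a), (lo_b, _) in zip(spans, spans[1:]):
                if lo_b <= hi_a:
                    raise ValueError(
                        f"overlapping domain spans within tier {tier}"
                    )

    def residues(self) -> list[tuple[int, str]]:
        """(construct position, one-letter code) pairs."""
        return list(enumerate(self.sequence, start=1))

    def domain_of(self, index: int, tier: int = 0) -> str | None:
        """Name of the tier-``tier`` domain containing construct ``index``."""
        for name in _TIERS[tier]:
            span = self.domain_spans.get(name)
            if span and span[0] <= index <= span[1]:
                return name
        return None


def make_construct(
    sequence: str,
    first_full_number: int = DEFAULT_FIRST_FULL_NUMBER,
    domain_spans: Mapping[str, tuple[int, int]] | None = None,
) -> Construct:
    """Build a validated :class:`Construct` from a one-letter sequence.

    Whitespace in ``sequence`` is stripped (the printed sequence is grouped
    in blocks of five).  Raises ``ValueError`` on an empty sequence or any
    character that is not a standard one-letter code, reporting the
    position of the offending character.
    """
    cleaned = "".join(sequence.split())
    spans = dict(domain_spans) if domain_spans is not None else dict(DEFAULT_DOMAIN_SPANS)
    if domain_spans is None and cleaned and len(cleaned) != len(SYD4_ETC_SEQUENCE):
        # default spans only make sense for the 57-mer; clamp to sequence
        n = len(cleaned)
        spans = {k: (lo, hi) for k, (lo, hi) in spans.items() if lo <= n}
        spans = {k: (lo, min(hi, n)) for k, (lo, hi) in spans.items()}
    return Construct(cleaned, first_full_number, spans)


def construct_from_fasta(
    path: str | Path,
    first_full_number: int = DEFAULT_FIRST_FULL_NUMBER,
    domain_spans: Mapping[str, tuple[int, int]] | None = None,
) -> Construct:
    """Read a single-record FASTA file into a :class:`Construct`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one FASTA record in {path}, found {len(records)}"
        )
    return make_construct(str(records[0].seq), first_full_number, domain_spans)


def count_residue(c: Construct, aa: str) -> int:
    """Exact count of occurrences of one amino-acid type.

    The construct contains e.g. a single asparagine; a doubled Asn peak
    count in an HSQC is therefore evidence of dimerization.
    """
    if len(aa) != 1 or aa.upper() not in AA_CODES:
        raise ValueError(f"invalid amino-acid code {aa!r}")
    return c.sequence.count(aa.upper())


def map_residue(c: Construct, construct_index: int) -> str:
    """Full-length residue label (e.g. ``'Ser179'``) for a construct position."""
    if not 1 <= construct_index <= len(c):
        raise ValueError(
            f"construct index {construct_index} out of range [1, {len(c)}]"
        )
    aa = c.sequence[construct_index - 1]
    return f"{AA_THREE_LETTER[aa]}{c.first_full_number + construct_index - 1}"


def full_number(c: Construct, construct_index: int) -> int:
    """Full-length residue number for a construct position."""
    if not 1 <= construct_index <= len(c):
        raise ValueError(
            f"construct index {construct_index} out of range [1, {len(c)}]"
        )
    return c.first_full_number + construct_index - 1


def find_gxxxg(c: Construct) -> list[tuple[int, int]]:
    """All GXXXG motif spans, as 1-based inclusive (start, end) pairs.

    Overlapping matches are all reported, ordered by start position.  The
    motif (glycines spaced four apart, one helix turn) mediates TM
    helix-helix dimerization.
    """
    seq = c.sequence
    return [
        (i + 1, i + 5)
        for i in range(len(seq) - 4)
        if seq[i] == "G" and seq[i + 4] == "G"
    ]
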