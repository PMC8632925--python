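"""Shared domain records: sequences, genomes, ORFs, gene annotations.

Coordinates are 1-based inclusive throughout the package; conversion to
0-based half-open happens only inside file-format code (GFF3/SAM writers).
For minus-strand features ``start`` is the plus-strand coordinate of the
*first transcribed base* (so start > end on the contig axis); format
writers re-order the interval where the format requires start <= end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_ROLES = ("cms", "nuclear_donor", "cytoplasmic_donor", "fertile_relative")

_ALPHABET = set("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One contig: uppercase nucleotide sequence over {A,C,G,T,N}."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord requires a non-empty id")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A truth/reference gene on a contig.

    ``ortholog_id`` links orthologous gene pairs across donor genomes;
    donor-unique genes carry ``ortholog_id=None``.
    """

    gene_id: str
    contig_id: str
    start: int  # 1-based, first base of start codon (plus-strand coordinate)
    end: int    # 1-based, last base of stop codon
    strand: str
    ortholog_id: Optional[str] = None

    def span(self) -> tuple[int, int]:
        """Plus-strand (low, high) interval."""
        return (min(self.start, self.end), max(self.start, self.end))

    def extract(self, contig: SequenceRecord) -> str:
        lo, hi = self.span()
        sub = contig.sequence[lo - 1 : hi]
        return sub if self.strand == "+" else revcomp(sub)


@dataclass
class GenomeRecord:
    """A labelled set of contigs for one line."""

    line_id: str
    role: str
    contigs: list[SequenceRecord] = field(default_factory=list)
    genes: list[GeneAnnotation] = field(default_factory=list)
    organelle: str = "mitochondrion"

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(
                f"role {self.role!r} not one of {VALID_ROLES}"
            )

    def contig(self, contig_id: str) -> SequenceRecord:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(f"{self.line_id}: no contig {contig_id!r}")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def gene_sequence(self, gene_id: str) -> str:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g.extract(self.contig(g.contig_id))
        raise KeyError(f"{self.line_id}: no gene {gene_id!r}")


@dataclass
class OrfRecord:
    """A predicted open reading frame.

    ``start`` is the contig position of the first base of the start codon and
    ``end`` the last base before the stop codon (both 1-based inclusive on the
    plus-strand axis; start > end for minus-strand ORFs). ``nt_sequence``
    excludes the stop codon, so nt_length == 3 * aa_length.
    """

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    nt_sequence: str
    aa_sequence: str
    truncated: bool = False
    wraps_origin: bool = False
    line_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.truncated:
            if len(self.nt_sequence) % 3 != 0:
                raise ValueError(f"{self.orf_id}: nt length not divisible by 3")
            if len(self.aa_sequence) * 3 != len(self.nt_sequence):
                raise ValueError(f"{self.orf_id}: aa/nt length mismatch")
            if not self.aa_sequence.startswith("M"):
                raise ValueError(f"{self.orf_id}: does not start with M")
            if "*" in self.aa_sequence:
                raise ValueError(f"{self.orf_id}: internal stop codon")

    @property
    def nt_length(self) -> int:
        return len(self.nt_sequence)

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)

    def span(self) -> tuple[int, int]:
        return (min(self.start, self.end), max(self.start, self.end))
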