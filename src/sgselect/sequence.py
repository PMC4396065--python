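"""Sequence and interval primitives shared by every pipeline stage.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open ``[start, end)`` on the
reference ('+') axis.  All user-facing I/O (CLI arguments, reports) is
1-based inclusive, the convention of genome browsers; conversion happens
only at the boundary (:meth:`GenomicInterval.from_1based` /
:meth:`GenomicInterval.to_1based_str`).

The alphabet is A, C, G, T, N.  Lower-case (soft-masked) input is
upper-cased and treated as ordinary sequence; how N behaves during
scanning and mismatch counting is defined by the modules that scan.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "Genome",
    "GenomicInterval",
    "GeneModel",
    "read_fasta",
    "extract_region",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_RE = re.compile(r"^[ACGTN]+$")


def reverse_complement(s: str) -> str:
    """Reverse complement of a nucleotide string (A<->T, C<->G, N<->N)."""
    if not _VALID_RE.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(f"invalid nucleotide characters: {bad}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named sequence.

    ``strand`` affects only how sequence is extracted (reverse complement
    for '-'); coordinates always refer to the '+' axis.
    """

    seq_name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.seq_name}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_name == other.seq_name
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, seq_name: str, pos: int) -> bool:
        return seq_name == self.seq_name and self.start <= pos < self.end

    @classmethod
    def from_1based(
        cls, seq_name: str, start1: int, end1: int, strand: str = "+"
    ) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (browser convention)."""
        return cls(seq_name, start1 - 1, end1, strand)

    @classmethod
    def parse_region(cls, text: str, strand: str = "+") -> "GenomicInterval":
        """Parse ``chrom:start-end`` (1-based inclusive; commas and en-dash ok)."""
        cleaned = text.replace(",", "").replace("–", "-")
        m = re.match(r"^([^:]+):(\d+)-(\d+)$", cleaned)
        if not m:
            raise ValueError(f"cannot parse region {text!r} (expected chrom:start-end)")
        return cls.from_1based(m.group(1), int(m.group(2)), int(m.group(3)), strand)

    def to_1based_str(self) -> str:
        return f"{self.seq_name}:{self.start + 1}-{self.end}"


@dataclass
class Genome:
    """In-memory genome: sequence name -> upper-case nucleotide string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            if not _VALID_RE.match(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"sequence {name!r} has invalid characters: {bad}")

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class GeneModel:
    """A gene as an ordered set of exons; introns are the gaps between them.

    Exons must be non-overlapping, sorted by start, and on one sequence.
    Exon/intron numbering follows gene order: for a '-'-strand gene,
    exon 1 is the right-most exon on the reference axis.
    """

    gene_name: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        names = {e.seq_name for e in self.exons}
        if len(names) != 1:
            raise ValueError("all exons must lie on one sequence")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError("exons must be sorted and non-overlapping")

    @property
    def seq_name(self) -> str:
        return self.exons[0].seq_name

    @property
    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.seq_name, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_name, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def exons_in_gene_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns_in_gene_order(self) -> list[GenomicInterval]:
        return self.introns if self.strand == "+" else list(reversed(self.introns))


def read_fasta(path) -> Genome:
    """Read a (multi-record) FASTA file into a :class:`Genome`.

    The record name is the header token before the first whitespace;
    sequence is upper-cased.  Duplicate names, empty files and
    non-nucleotide characters (other than N) are rejected.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA record name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(sequences)


def extract_region(g: Genome, iv: GenomicInterval) -> str:
    """Sequence of ``iv``; for '-' strand the reverse complement is returned."""
    if iv.seq_name not in g:
        raise KeyError(f"unknown sequence {iv.seq_name!r}")
    if iv.end > g.length(iv.seq_name):
        raise ValueError(
            f"interval {iv.to_1based_str()} exceeds sequence length "
            f"{g.length(iv.seq_name)}"
        )
    sub = g[iv.seq_name][iv.start : iv.end]
    return sub if iv.strand == "+" else reverse_complement(sub)
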