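"""Known-variant screening of candidate sites.

A SNP (or any dbSNP-style variant) inside a candidate's 23-nt footprint
— protospacer or PAM — can change cleavage efficiency between
individuals, so candidates are scored by the number of overlapping known
variants and "no known variant" can be required during selection.  The
PAM is deliberately part of the footprint: a PAM-disrupting variant
abolishes cleavage outright.
"""

from __future__ import annotations

from dataclasses import dataclass

from .candidates import CandidateSite

__all__ = ["VariantRecord", "read_vcf_minimal", "count_overlapping_snps"]


@dataclass(frozen=True)
class VariantRecord:
    """The CHROM/POS/ID/REF/ALT core of a VCF record (POS is 1-based)."""

    seq_name: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"POS must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("REF must be non-empty")

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive reference span covered by the REF allele."""
        return self.pos, self.pos + len(self.ref) - 1


def read_vcf_minimal(path) -> list[VariantRecord]:
    """Read CHROM, POS, ID, REF, ALT from an uncompressed VCF 4.x file.

    Header lines are skipped; records come back in file order.  Only the
    five leading columns are consumed — genotypes, INFO and filters are
    ignored.  A data line with fewer than five columns is rejected with
    its line number.
    """
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 5 VCF columns, got {len(fields)}"
                )
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer POS") from exc
            records.append(
                VariantRecord(fields[0], pos, fields[2], fields[3], fields[4])
            )
    return records


def count_overlapping_snps(c: CandidateSite, variants: list[VariantRecord]) -> int:
    """Variants whose reference span intersects the full 23-nt footprint.

    Multi-nucleotide REF alleles overlap by their whole span; ALT plays
    no role.  No frequency filtering: any known variant counts.
    """
    fp_start, fp_end = c.site.start + 1, c.site.end  # 1-based inclusive
    n = 0
    for v in variants:
        if v.seq_name != c.site.seq_name:
            continue
        v_start, v_end = v.span
        if v_start <= fp_end and fp_start <= v_end:
            n += 1
    return n
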