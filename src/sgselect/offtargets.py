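"""Exhaustive genome-wide off-target search with mismatch tolerance.

An off-target of a 20-nt protospacer is any 23-nt genomic window, on
either strand, whose last three bases match the NGG PAM and whose first
twenty bases differ from the protospacer at no more than ``max_mm``
positions (Hamming distance; no weighting — PAM-proximal mismatches are
known to matter more on average, but not strictly, so we count plainly).
The leading-G constraint applies only to candidate selection (it is an
expression-construct requirement), never to off-target windows.

The search is seeded by the pigeonhole principle: the protospacer is
split into ``max_mm + 1`` contiguous chunks, so any window within the
mismatch budget matches at least one chunk exactly.  Every exact chunk
occurrence proposes a window, which is then verified in full.  The
result is exhaustive — identical to a brute-force sliding-window scan —
at a fraction of the cost.

N policy: a position where either base is N counts as a mismatch; a
window whose PAM contains N is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .candidates import PROTO_LEN, SITE_LEN, CandidateSite, MIDPOINT_OFFSET
from .sequence import Genome, GenomicInterval, reverse_complement

__all__ = [
    "OffTargetHit",
    "HomologSimilaritySummary",
    "count_mismatches",
    "find_offtargets",
    "summarize_homolog_similarity",
]


@dataclass(frozen=True)
class OffTargetHit:
    """One genomic match of a protospacer with <= k mismatches and NGG PAM.

    ``mismatch_positions`` are 1-based along the protospacer, 1 being the
    PAM-distal (5') end and 20 the PAM-proximal end.
    ``matched_sequence`` is the 23-nt window read 5'->3' on the hit strand.
    """

    candidate_label: str
    site: GenomicInterval
    strand: str
    matched_sequence: str
    mismatch_count: int
    mismatch_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.mismatch_count != len(self.mismatch_positions):
            raise ValueError("mismatch_count must equal |mismatch_positions|")


def count_mismatches(a: str, b: str) -> tuple[int, frozenset[int]]:
    """Hamming comparison of two 20-nt strings.

    Returns (count, 1-based positions).  Any position where either base
    is N counts as a mismatch (N never matches, not even N vs N).
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    positions = frozenset(
        i + 1
        for i, (x, y) in enumerate(zip(a, b))
        if x != y or x == "N"
    )
    return len(positions), positions


def _pigeonhole_chunks(proto: str, n_chunks: int) -> list[tuple[int, str]]:
    """Split ``proto`` into ``n_chunks`` near-equal contiguous (offset, seq) chunks."""
    base, rem = divmod(len(proto), n_chunks)
    chunks = []
    pos = 0
    for j in range(n_chunks):
        length = base + (1 if j < rem else 0)
        chunks.append((pos, proto[pos : pos + length]))
        pos += length
    return chunks


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_offtargets(
    g: Genome, c: CandidateSite, max_mm: int
) -> list[OffTargetHit]:
    """All 23-nt windows matching ``c.protospacer`` within ``max_mm`` mismatches.

    The window identical to the candidate's own locus (same coordinates
    and strand) is excluded; a second perfect match elsewhere IS reported
    as a 0-mismatch hit.  Output is sorted by (sequence, start, strand).
    """
    if not 0 <= max_mm <= 5:
        raise ValueError(f"max_mm must be in [0, 5], got {max_mm}")
    proto = c.protospacer
    chunks = _pigeonhole_chunks(proto, max_mm + 1)
    hits: list[OffTargetHit] = []
    for name, seq in g.sequences.items():
        n = len(seq)
        for strand in ("+", "-"):
            s = seq if strand == "+" else reverse_complement(seq)
            starts: set[int] = set()
            for offset, chunk in chunks:
                for occ in _find_all(s, chunk):
                    start = occ - offset
                    if 0 <= start <= len(s) - SITE_LEN:
                        starts.add(start)
            for start in starts:
                window = s[start : start + SITE_LEN]
                pam = window[PROTO_LEN:]
                if "N" in pam or pam[1] != "G" or pam[2] != "G":
                    continue
                count, positions = count_mismatches(proto, window[:PROTO_LEN])
                if count > max_mm:
                    continue
                ref_start = start if strand == "+" else n - start - SITE_LEN
                site = GenomicInterval(name, ref_start, ref_start + SITE_LEN, strand)
                if (
                    site.seq_name == c.site.seq_name
                    and site.start == c.site.start
                    and strand == c.strand
                ):
                    continue  # the on-target locus itself
                hits.append(
                    OffTargetHit(
                        candidate_label=c.label,
                        site=site,
                        strand=strand,
                        matched_sequence=window,
                        mismatch_count=count,
                        mismatch_positions=positions,
                    )
                )
    hits.sort(key=lambda h: (h.site.seq_name, h.site.start, h.strand))
    return hits


@dataclass(frozen=True)
class HomologSimilaritySummary:
    """Near-identical off-targets of one candidate inside named homolog regions.

    "Near-identical" means at most one mismatch — a guide that keeps such
    a site in a paralog cannot discriminate the target gene from it.
    """

    candidate_label: str
    n_near_identical_at_homolog: int
    homolog_names: tuple[str, ...]


def summarize_homolog_similarity(
    hits: list[OffTargetHit],
    homolog_regions: dict[str, GenomicInterval],
    max_mm: int = 1,
) -> HomologSimilaritySummary:
    """Count hits with <= ``max_mm`` mismatches whose midpoint lies in a homolog."""
    label = hits[0].candidate_label if hits else ""
    count = 0
    names: list[str] = []
    for h in hits:
        if h.mismatch_count > max_mm:
            continue
        mid = h.site.start + MIDPOINT_OFFSET
        for name, region in homolog_regions.items():
            if region.contains_point(h.site.seq_name, mid):
                count += 1
                if name not in names:
                    names.append(name)
                break
    return HomologSimilaritySummary(label, count, tuple(names))
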