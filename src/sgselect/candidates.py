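"""Candidate CRISPR target-site enumeration.

A candidate site matches the 23-nt pattern G-N19-NGG on either strand:
a leading G (required for U6-promoter-driven sgRNA expression), a 19-nt
body, and the Cas9 NGG protospacer-adjacent motif.  Sites are reported
on the reference axis with a strand flag; the protospacer and PAM are
given 5'->3' on the site's own strand.

Each site is assigned to exactly one gene compartment (exon or intron)
by the position of its protospacer midpoint (offset 11 of the 23-nt
footprint, which is strand-symmetric), and labelled "E{k}-{i}" /
"I{k}-{i}": compartment k in gene order, site i by ascending genomic
start within the compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .sequence import GeneModel, Genome, GenomicInterval, extract_region, reverse_complement

__all__ = ["CandidateSite", "scan_candidates", "assign_labels", "at_percent"]

SITE_LEN = 23
PROTO_LEN = 20
MIDPOINT_OFFSET = 11  # 0-based offset within the footprint; 22 - 11 == 11, so strand-free


@dataclass(frozen=True)
class CandidateSite:
    """One G-N19-NGG locus.

    ``at_percent`` is 100 x (A+T count)/20 over the protospacer only;
    the fixed NGG PAM is excluded so it cannot bias composition.
    """

    label: str
    site: GenomicInterval
    strand: str
    protospacer: str
    pam: str
    region_class: str
    at_percent: float

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTO_LEN or len(self.pam) != 3:
            raise ValueError("protospacer must be 20 nt and PAM 3 nt")
        if self.protospacer[0] != "G":
            raise ValueError("protospacer must start with G")
        if self.pam[1:] != "GG":
            raise ValueError("PAM must match NGG")

    @property
    def sequence(self) -> str:
        """Full 23-nt site sequence on its own strand."""
        return self.protospacer + self.pam

    @property
    def midpoint(self) -> int:
        return self.site.start + MIDPOINT_OFFSET


def at_percent(protospacer: str) -> float:
    """AT content of a 20-nt protospacer as a percentage."""
    if len(protospacer) != PROTO_LEN:
        raise ValueError(f"protospacer must be {PROTO_LEN} nt, got {len(protospacer)}")
    if set(protospacer) - set("ACGT"):
        raise ValueError("protospacer must contain only A,C,G,T")
    return 100.0 * (protospacer.count("A") + protospacer.count("T")) / PROTO_LEN


def _classify(midpoint: int, seq_name: str, model: GeneModel) -> str:
    for exon in model.exons:
        if exon.contains_point(seq_name, midpoint):
            return "exon"
    return "intron"


def scan_candidates(
    g: Genome, region: GenomicInterval, model: GeneModel
) -> list[CandidateSite]:
    """Enumerate every G-N19-NGG site in ``region`` on both strands.

    Overlapping sites are kept; 23-nt windows containing N are skipped
    (an undefined base can neither satisfy the pattern nor be scored).
    A region shorter than 23 nt yields an empty list.  Labels are left
    empty; use :func:`assign_labels`.
    """
    fwd = extract_region(
        g, GenomicInterval(region.seq_name, region.start, region.end, "+")
    )
    sites: list[CandidateSite] = []
    for i in range(len(fwd) - SITE_LEN + 1):
        w = fwd[i : i + SITE_LEN]
        if "N" in w:
            continue
        abs_start = region.start + i
        mid = abs_start + MIDPOINT_OFFSET
        iv_args = (region.seq_name, abs_start, abs_start + SITE_LEN)
        # '+' strand: G at 0, GG at 21-22
        if w[0] == "G" and w[21] == "G" and w[22] == "G":
            proto, pam = w[:PROTO_LEN], w[PROTO_LEN:]
            sites.append(
                CandidateSite(
                    label="",
                    site=GenomicInterval(*iv_args, "+"),
                    strand="+",
                    protospacer=proto,
                    pam=pam,
                    region_class=_classify(mid, region.seq_name, model),
                    at_percent=at_percent(proto),
                )
            )
        # '-' strand: pattern on the reverse complement <=> CCN...C on '+'
        if w[0] == "C" and w[1] == "C" and w[22] == "C":
            rc = reverse_complement(w)
            proto, pam = rc[:PROTO_LEN], rc[PROTO_LEN:]
            sites.append(
                CandidateSite(
                    label="",
                    site=GenomicInterval(*iv_args, "-"),
                    strand="-",
                    protospacer=proto,
                    pam=pam,
                    region_class=_classify(mid, region.seq_name, model),
                    at_percent=at_percent(proto),
                )
            )
    return sites


def assign_labels(
    sites: list[CandidateSite], model: GeneModel
) -> list[CandidateSite]:
    """Label sites "E{k}-{i}" / "I{k}-{i}" and sort by genomic start.

    Compartments are numbered 1..n in gene order (for a '-'-strand gene
    the right-most exon is exon 1); within a compartment, sites are
    numbered by ascending genomic start.  A site whose midpoint falls
    outside every exon and intron of the model is an error.
    """
    compartments: list[tuple[str, int, GenomicInterval]] = []
    for k, exon in enumerate(model.exons_in_gene_order(), start=1):
        compartments.append(("E", k, exon))
    for k, intron in enumerate(model.introns_in_gene_order(), start=1):
        compartments.append(("I", k, intron))

    def find_compartment(site: CandidateSite) -> tuple[str, int]:
        wanted = "E" if site.region_class == "exon" else "I"
        for kind, k, iv in compartments:
            if kind == wanted and iv.contains_point(site.site.seq_name, site.midpoint):
                return kind, k
        raise ValueError(
            f"site at {site.site.to_1based_str()} ({site.strand}) lies outside "
            f"all exons and introns of {model.gene_name}"
        )

    ordered = sorted(sites, key=lambda s: (s.site.start, s.strand))
    counters: dict[tuple[str, int], int] = {}
    labelled = []
    for site in ordered:
        key = find_compartment(site)
        counters[key] = counters.get(key, 0) + 1
        labelled.append(replace(site, label=f"{key[0]}{key[1]}-{counters[key]}"))
    return labelled
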