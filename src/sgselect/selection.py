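"""Multi-criteria filtering and deterministic ranking of candidate sites.

The selection logic operationalizes the design rules for discriminating
a gene from close homologs: prefer intron sites (their homology is less
conserved, so off-targets at paralogs are rarer and coding damage
elsewhere is lower), require zero known variants, keep AT content
moderate, and reject guides containing common regulatory boxes.

Among the survivors, ranking is lexicographic: fewest off-targets
genome-wide first, then fewest near-identical hits at homologs, then
fewest exonic off-targets, then fewest TFBS off-targets, ties broken by
genomic start.  The ordering is total and independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .candidates import CandidateSite

__all__ = ["SelectionCriteria", "RankedCandidate", "apply_filters", "rank_candidates"]


@dataclass(frozen=True)
class SelectionCriteria:
    """Filter thresholds; AT bounds default to the moderate [25, 75] band."""

    require_intron: bool = True
    require_zero_snps: bool = True
    at_min: float = 25.0
    at_max: float = 75.0
    forbid_common_motifs: bool = True
    max_mismatches: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.at_min < self.at_max <= 100:
            raise ValueError("need 0 <= at_min < at_max <= 100")


@dataclass(frozen=True)
class RankedCandidate:
    """A candidate joined to its off-target / SNP / motif metrics."""

    candidate: CandidateSite
    n_offtargets_total: int = 0
    n_offtargets_exon: int = 0
    n_offtargets_tfbs: int = 0
    n_homolog_near_identical: int = 0
    snp_count: int = 0
    common_motifs: tuple[str, ...] = ()
    passed: bool = False
    rank: int | None = None


def apply_filters(
    rcs: list[RankedCandidate], crit: SelectionCriteria
) -> list[RankedCandidate]:
    """Set each candidate's ``passed`` flag against the criteria."""
    out = []
    for rc in rcs:
        c = rc.candidate
        ok = True
        if crit.require_intron and c.region_class != "intron":
            ok = False
        if crit.require_zero_snps and rc.snp_count > 0:
            ok = False
        if not crit.at_min <= c.at_percent <= crit.at_max:
            ok = False
        if crit.forbid_common_motifs and rc.common_motifs:
            ok = False
        out.append(replace(rc, passed=ok, rank=None))
    return out


def _rank_key(rc: RankedCandidate):
    return (
        rc.n_offtargets_total,
        rc.n_homolog_near_identical,
        rc.n_offtargets_exon,
        rc.n_offtargets_tfbs,
        rc.candidate.site.seq_name,
        rc.candidate.site.start,
        rc.candidate.strand,
    )


def rank_candidates(rcs: list[RankedCandidate]) -> list[RankedCandidate]:
    """Order passing candidates (ranks 1..m) followed by failed ones.

    The returned list holds every input candidate; failed candidates keep
    ``rank=None`` and trail the passing ones in the same deterministic
    order.
    """
    passing = sorted((rc for rc in rcs if rc.passed), key=_rank_key)
    failing = sorted((rc for rc in rcs if not rc.passed), key=_rank_key)
    ranked = [replace(rc, rank=i) for i, rc in enumerate(passing, start=1)]
    return ranked + [replace(rc, rank=None) for rc in failing]
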