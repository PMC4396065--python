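"""End-to-end pipeline: scan -> off-target search -> annotate -> screen -> rank.

Composes the stage modules into one run over a genome + annotation
bundle and writes the report files.  All report coordinates are 1-based
inclusive; reports are byte-deterministic for identical inputs (logging,
including any timestamps, goes to stderr only).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import (
    AnnotationSet,
    OffTargetAnnotation,
    classify_offtargets,
    read_bed,
    tf_enrichment_panel,
)
from .candidates import CandidateSite, assign_labels, scan_candidates
from .motifs import flag_common_elements, read_jaspar_pfm
from .offtargets import OffTargetHit, find_offtargets, summarize_homolog_similarity
from .selection import RankedCandidate, SelectionCriteria, apply_filters, rank_candidates
from .sequence import GeneModel, Genome, GenomicInterval, read_fasta
from .variants import count_overlapping_snps, read_vcf_minimal

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "candidates_to_df",
    "hits_to_df",
    "ranked_to_df",
]

log = logging.getLogger("sgselect")


@dataclass
class PipelineConfig:
    """Everything one full run needs; paths may be None for omitted stages."""

    genome_path: str
    region: str  # "chrom:start-end", 1-based inclusive
    exons_bed: str
    peaks_bed: str | None = None
    variants_vcf: str | None = None
    motifs_jaspar: str | None = None
    homolog_regions: dict[str, str] = field(default_factory=dict)  # name -> region
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    max_mismatches: int = 3
    gene_strand: str = "+"
    output_dir: str = "sgselect_out"


def candidates_to_df(sites: list[CandidateSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [s.label for s in sites],
            "chrom": [s.site.seq_name for s in sites],
            "start": [s.site.start + 1 for s in sites],
            "end": [s.site.end for s in sites],
            "strand": [s.strand for s in sites],
            "protospacer": [s.protospacer for s in sites],
            "pam": [s.pam for s in sites],
            "region_class": [s.region_class for s in sites],
            "at_percent": [s.at_percent for s in sites],
        }
    )


def hits_to_df(hits: list[OffTargetHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "candidate_label": [h.candidate_label for h in hits],
            "chrom": [h.site.seq_name for h in hits],
            "start": [h.site.start + 1 for h in hits],
            "end": [h.site.end for h in hits],
            "strand": [h.strand for h in hits],
            "matched_sequence": [h.matched_sequence for h in hits],
            "mismatch_count": [h.mismatch_count for h in hits],
            "mismatch_positions": [
                ",".join(str(p) for p in sorted(h.mismatch_positions)) for h in hits
            ],
        }
    )


def ranked_to_df(rcs: list[RankedCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [r.candidate.label for r in rcs],
            "chrom": [r.candidate.site.seq_name for r in rcs],
            "start": [r.candidate.site.start + 1 for r in rcs],
            "end": [r.candidate.site.end for r in rcs],
            "strand": [r.candidate.strand for r in rcs],
            "protospacer": [r.candidate.protospacer for r in rcs],
            "pam": [r.candidate.pam for r in rcs],
            "region_class": [r.candidate.region_class for r in rcs],
            "at_percent": [r.candidate.at_percent for r in rcs],
            "n_offtargets_total": [r.n_offtargets_total for r in rcs],
            "n_offtargets_exon": [r.n_offtargets_exon for r in rcs],
            "n_offtargets_tfbs": [r.n_offtargets_tfbs for r in rcs],
            "n_offtargets_ncdna": [
                r.n_offtargets_total - r.n_offtargets_exon - r.n_offtargets_tfbs
                for r in rcs
            ],
            "n_homolog_near_identical": [r.n_homolog_near_identical for r in rcs],
            "snp_count": [r.snp_count for r in rcs],
            "common_motifs": [",".join(r.common_motifs) for r in rcs],
            "passed": [r.passed for r in rcs],
            "rank": [r.rank if r.rank is not None else "" for r in rcs],
        }
    )


def _gene_model_from_bed(
    exons: list[GenomicInterval], region: GenomicInterval, strand: str
) -> GeneModel:
    inside = sorted(
        (e for e in exons if e.seq_name == region.seq_name
         and e.start >= region.start and e.end <= region.end),
        key=lambda e: e.start,
    )
    if not inside:
        raise ValueError("no exons from the BED file fall inside the scan region")
    return GeneModel("target_gene", strand, inside)


def build_metrics(
    sites: list[CandidateSite],
    genome: Genome,
    annotations: AnnotationSet,
    variants,
    homolog_regions: dict[str, GenomicInterval],
    max_mm: int,
) -> tuple[list[RankedCandidate], list[OffTargetHit], dict[str, list[OffTargetAnnotation]]]:
    """Off-target search + annotation + screening for every candidate."""
    rcs = []
    all_hits: list[OffTargetHit] = []
    per_candidate_anns: dict[str, list[OffTargetAnnotation]] = {}
    for site in sites:
        hits = find_offtargets(genome, site, max_mm)
        anns = classify_offtargets(hits, annotations)
        summary = summarize_homolog_similarity(hits, homolog_regions)
        all_hits.extend(hits)
        per_candidate_anns[site.label] = anns
        rcs.append(
            RankedCandidate(
                candidate=site,
                n_offtargets_total=len(hits),
                n_offtargets_exon=sum(1 for a in anns if a.category == "exon"),
                n_offtargets_tfbs=sum(1 for a in anns if a.category == "tfbs"),
                n_homolog_near_identical=summary.n_near_identical_at_homolog,
                snp_count=count_overlapping_snps(site, variants) if variants else 0,
                common_motifs=tuple(flag_common_elements(site)),
            )
        )
    return rcs, all_hits, per_candidate_anns


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report files; returns a summary dict."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = read_fasta(cfg.genome_path)
    region = GenomicInterval.parse_region(cfg.region)
    exon_ivs = read_bed(cfg.exons_bed)
    model = _gene_model_from_bed(exon_ivs, region, cfg.gene_strand)
    peaks = read_bed(cfg.peaks_bed, name_field=3) if cfg.peaks_bed else []
    annotations = AnnotationSet(exons=exon_ivs, tf_peaks=peaks)
    variants = read_vcf_minimal(cfg.variants_vcf) if cfg.variants_vcf else []
    if cfg.motifs_jaspar:
        read_jaspar_pfm(cfg.motifs_jaspar)  # validated; panel TFs come from peaks
    homologs = {
        name: GenomicInterval.parse_region(text)
        for name, text in cfg.homolog_regions.items()
    }

    sites = assign_labels(scan_candidates(genome, region, model), model)
    log.info("scan: %d candidate sites in %s", len(sites), region.to_1based_str())

    rcs, all_hits, per_candidate_anns = build_metrics(
        sites, genome, annotations, variants, homologs, cfg.max_mismatches
    )
    log.info("off-target search: %d hits total (max %d mismatches)",
             len(all_hits), cfg.max_mismatches)

    rcs = rank_candidates(apply_filters(rcs, cfg.criteria))
    n_pass = sum(1 for r in rcs if r.passed)
    log.info("selection: %d of %d candidates pass filters", n_pass, len(rcs))

    enrich_rows = []
    for label in sorted(per_candidate_anns):
        anns = per_candidate_anns[label]
        if not anns:
            continue
        for res, q, flagged in tf_enrichment_panel(anns, annotations, genome):
            enrich_rows.append(
                {
                    "candidate_label": label,
                    "tf": res.tf_name,
                    "hits_in_peaks": res.hits_in_peaks,
                    "total_hits": res.total_hits,
                    "background": res.background_fraction,
                    "p_value": res.p_value,
                    "q_value": q,
                    "enriched": flagged,
                }
            )

    candidates_to_df(sites).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    hits_to_df(all_hits).to_csv(outdir / "offtargets.tsv", sep="\t", index=False)
    pd.DataFrame(
        enrich_rows,
        columns=["candidate_label", "tf", "hits_in_peaks", "total_hits",
                 "background", "p_value", "q_value", "enriched"],
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    ranked_to_df(rcs).to_csv(outdir / "master.tsv", sep="\t", index=False)

    top = next((r for r in rcs if r.rank == 1), None)
    recommendation = None
    if top is not None:
        recommendation = {
            "label": top.candidate.label,
            "position": top.candidate.site.to_1based_str(),
            "strand": top.candidate.strand,
            "sequence": top.candidate.sequence,
            "protospacer": top.candidate.protospacer,
            "pam": top.candidate.pam,
            "region_class": top.candidate.region_class,
            "at_percent": top.candidate.at_percent,
            "n_offtargets_total": top.n_offtargets_total,
            "n_offtargets_exon": top.n_offtargets_exon,
            "n_offtargets_tfbs": top.n_offtargets_tfbs,
            "n_homolog_near_identical": top.n_homolog_near_identical,
            "snp_count": top.snp_count,
        }
    else:
        log.warning("no candidate passed the selection criteria")
    with open(outdir / "recommendation.json", "w") as fh:
        json.dump(recommendation, fh, indent=1)

    return {
        "n_candidates": len(sites),
        "n_exon_candidates": sum(1 for s in sites if s.region_class == "exon"),
        "n_intron_candidates": sum(1 for s in sites if s.region_class == "intron"),
        "n_offtarget_hits": len(all_hits),
        "n_passing": n_pass,
        "recommendation": recommendation,
        "ranked": rcs,
        "sites": sites,
    }
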