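"""Synthetic test locus: a gene plus a tandem-duplicated, diverged paralog.

Real guide-discrimination problems arise at loci like the human
beta-globin cluster, where tandem duplication left near-identical
paralogs (HBB/HBD) next to each other.  This module generates a fully
self-contained stand-in: random background, a multi-exon gene, a spacer,
a paralog copy of the gene carrying i.i.d. substitutions, planted TF
peaks over motif instances in the background, and planted SNPs — with a
truth table for every random decision, so every pipeline stage can be
validated against ground truth without downloading a genome.

Divergence modes
----------------
``conservation_biased`` (default): exons substitute at 0.3x the intron
rate, emulating purifying selection on coding sequence — the mechanism
that makes exon-derived guides retain near-identical paralog off-targets
while intron-derived guides escape them.  ``uniform``: one rate
everywhere.  ``paralog_divergence`` is the intron (maximum) rate.

Everything is drawn from one seeded generator in a fixed order, so equal
seeds give byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import AnnotationSet
from .motifs import PositionFrequencyMatrix, write_jaspar_pfm
from .sequence import GeneModel, Genome, GenomicInterval
from .variants import VariantRecord

__all__ = [
    "LocusSpec",
    "LocusTruth",
    "generate_locus",
    "write_fixture",
    "plant_offtargets",
    "synthetic_nfya_pfm",
]

_BASES = np.array(list("ACGT"))


def synthetic_nfya_pfm() -> PositionFrequencyMatrix:
    """Synthetic stand-in for an NF-YA binding-motif count matrix.

    Built around the CCAAT core the factor recognizes, with weakly
    informative flanks; it is NOT a database matrix, just a realistic
    shape for testing motif scanning and peak planting.
    """
    #            flank  flank  C    C    A    A    T   flank  flank  flank
    counts = np.array(
        [
            [10.0, 30.0, 1.0, 0.0, 95.0, 97.0, 2.0, 20.0, 25.0, 30.0],  # A
            [30.0, 20.0, 96.0, 99.0, 1.0, 1.0, 1.0, 30.0, 25.0, 20.0],  # C
            [40.0, 20.0, 2.0, 1.0, 3.0, 1.0, 1.0, 30.0, 25.0, 30.0],  # G
            [20.0, 30.0, 1.0, 0.0, 1.0, 1.0, 96.0, 20.0, 25.0, 20.0],  # T
        ]
    )
    return PositionFrequencyMatrix("NFYA_synthetic", counts)


@dataclass
class LocusSpec:
    """Parameters of one synthetic locus.

    Default exon/intron lengths mimic a compact three-exon, two-intron
    globin-like gene (~1.6 kb span).
    """

    seed: int = 0
    background_length: int = 20_000
    gene_exon_lengths: list[int] = field(default_factory=lambda: [142, 223, 261])
    gene_intron_lengths: list[int] = field(default_factory=lambda: [130, 850])
    paralog_divergence: float = 0.07
    divergence_mode: str = "conservation_biased"  # or "uniform"
    exon_rate_factor: float = 0.3
    n_snps: int = 20
    tf_motif: PositionFrequencyMatrix = field(default_factory=synthetic_nfya_pfm)
    n_tf_peaks: int = 8
    gc_content: float = 0.5
    spacer_length: int = 600
    seq_name: str = "chrS"
    peak_halfwidth: int = 75

    def __post_init__(self) -> None:
        if len(self.gene_intron_lengths) != len(self.gene_exon_lengths) - 1:
            raise ValueError("need one fewer intron than exons")
        if any(l <= 0 for l in self.gene_exon_lengths + self.gene_intron_lengths):
            raise ValueError("exon/intron lengths must be positive")
        if not 0 <= self.paralog_divergence <= 0.3:
            raise ValueError("paralog_divergence must be in [0, 0.3]")
        if self.divergence_mode not in ("conservation_biased", "uniform"):
            raise ValueError(f"unknown divergence mode {self.divergence_mode!r}")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")

    @property
    def gene_length(self) -> int:
        return sum(self.gene_exon_lengths) + sum(self.gene_intron_lengths)


@dataclass
class LocusTruth:
    """A generated locus plus the ground truth of every planted feature."""

    spec: LocusSpec
    genome: Genome
    gene_model: GeneModel
    paralog_region: GenomicInterval
    planted_snps: list[VariantRecord]
    planted_peaks: AnnotationSet
    substitution_positions: list[int]  # genome coordinates within the paralog copy

    @property
    def gene_region(self) -> GenomicInterval:
        return self.gene_model.span


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _substitute(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def generate_locus(spec: LocusSpec) -> LocusTruth:
    """Deterministically generate a locus from its spec.

    Genome layout: left background | gene | spacer | paralog | right
    background.  The paralog is the gene sequence with i.i.d.
    substitutions; its exon copies are part of the annotation's exon set
    (they are coding sequence too).  SNPs are placed uniformly without
    replacement over the gene span; TF peaks sit over motif instances
    written into the background.
    """
    rng = np.random.default_rng(spec.seed)
    name = spec.seq_name

    left_len = spec.background_length // 2
    right_len = spec.background_length - left_len
    gene_len = spec.gene_length
    needed = gene_len + spec.spacer_length + gene_len
    if left_len + right_len < 2 * (spec.peak_halfwidth + spec.tf_motif.length):
        raise ValueError("background too short for the requested features")

    # 1. sequences, in fixed order
    left_bg = _random_seq(rng, left_len, spec.gc_content)
    gene_seq = _random_seq(rng, gene_len, spec.gc_content)
    spacer = _random_seq(rng, spec.spacer_length, spec.gc_content)
    right_bg = _random_seq(rng, right_len, spec.gc_content)

    gene_start = left_len
    # exon/intron structure relative to gene start
    exons: list[GenomicInterval] = []
    offset = 0
    is_exonic = np.zeros(gene_len, dtype=bool)
    for i, elen in enumerate(spec.gene_exon_lengths):
        exons.append(GenomicInterval(name, gene_start + offset, gene_start + offset + elen, "+"))
        is_exonic[offset : offset + elen] = True
        if i < len(spec.gene_intron_lengths):
            offset += elen + spec.gene_intron_lengths[i]
        else:
            offset += elen
    gene_model = GeneModel("GENE", "+", exons)

    # 2. paralog: substitute gene sequence position by position
    if spec.divergence_mode == "uniform":
        rates = np.full(gene_len, spec.paralog_divergence)
    else:
        rates = np.where(
            is_exonic,
            spec.exon_rate_factor * spec.paralog_divergence,
            spec.paralog_divergence,
        )
    sub_mask = rng.random(gene_len) < rates
    paralog_chars = list(gene_seq)
    paralog_start = gene_start + gene_len + spec.spacer_length
    substitution_positions = []
    for i in np.flatnonzero(sub_mask):
        paralog_chars[i] = _substitute(gene_seq[i], rng)
        substitution_positions.append(paralog_start + int(i))
    paralog_seq = "".join(paralog_chars)
    paralog_region = GenomicInterval(name, paralog_start, paralog_start + gene_len, "+")

    full = left_bg + gene_seq + spacer + paralog_seq + right_bg
    total_len = len(full)

    # 3. TF peaks over motif instances written into the right background
    motif_seq = spec.tf_motif.consensus
    L = spec.tf_motif.length
    bg_start = paralog_start + gene_len
    slot = 2 * spec.peak_halfwidth + L
    max_peaks = (total_len - bg_start) // slot
    if spec.n_tf_peaks > max_peaks:
        raise ValueError(
            f"background can hold at most {max_peaks} peaks, asked for {spec.n_tf_peaks}"
        )
    chars = list(full)
    peaks: list[tuple[str, GenomicInterval]] = []
    if spec.n_tf_peaks > 0:
        slots = rng.choice(max_peaks, size=spec.n_tf_peaks, replace=False)
        for s in sorted(int(x) for x in slots):
            motif_at = bg_start + s * slot + spec.peak_halfwidth
            chars[motif_at : motif_at + L] = motif_seq
            peaks.append(
                (
                    spec.tf_motif.motif_name,
                    GenomicInterval(
                        name,
                        max(0, motif_at - spec.peak_halfwidth),
                        min(total_len, motif_at + L + spec.peak_halfwidth),
                        "+",
                    ),
                )
            )
    full = "".join(chars)

    # 4. SNPs uniformly without replacement over the gene span
    snps: list[VariantRecord] = []
    if spec.n_snps > 0:
        positions = rng.choice(gene_len, size=min(spec.n_snps, gene_len), replace=False)
        for j, p in enumerate(sorted(int(x) for x in positions), start=1):
            gpos = gene_start + p
            ref = full[gpos]
            snps.append(
                VariantRecord(name, gpos + 1, f"snp{j}", ref, _substitute(ref, rng))
            )

    paralog_exons = [
        GenomicInterval(name, e.start - gene_start + paralog_start,
                        e.end - gene_start + paralog_start, "+")
        for e in exons
    ]
    annotations = AnnotationSet(exons=exons + paralog_exons, tf_peaks=peaks)

    return LocusTruth(
        spec=spec,
        genome=Genome({name: full}),
        gene_model=gene_model,
        paralog_region=paralog_region,
        planted_snps=snps,
        planted_peaks=annotations,
        substitution_positions=substitution_positions,
    )


def plant_offtargets(
    background: str,
    protospacer: str,
    n: int,
    max_mm: int,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, str, int]]]:
    """Overwrite ``n`` mutated protospacer+PAM copies into a background.

    Each copy carries a number of substitutions drawn uniformly from
    0..max_mm (in the 20-nt protospacer only) and an N-GG PAM, on a
    random strand, at non-overlapping positions.  Returns the new
    sequence and a truth list of (start, strand, n_substitutions).
    """
    from .sequence import reverse_complement  # local import avoids a cycle

    site_len = len(protospacer) + 3
    slot = site_len + 2
    max_n = len(background) // slot
    if n > max_n:
        raise ValueError(f"background fits at most {max_n} planted sites")
    chars = list(background)
    truth = []
    slots = rng.choice(max_n, size=n, replace=False)
    for s in sorted(int(x) for x in slots):
        start = s * slot + 1
        n_sub = int(rng.integers(0, max_mm + 1))
        proto = list(protospacer)
        if n_sub:
            for i in rng.choice(len(proto), size=n_sub, replace=False):
                proto[i] = _substitute(proto[i], rng)
        pam = "ACGT"[rng.integers(0, 4)] + "GG"
        insert = "".join(proto) + pam
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            insert = reverse_complement(insert)
        chars[start : start + site_len] = insert
        truth.append((start, strand, n_sub))
    return "".join(chars), truth


def write_fixture(t: LocusTruth, outdir) -> dict[str, Path]:
    """Write FASTA / BED / VCF / JASPAR / truth-JSON files for a locus.

    Every file round-trips through the package's own readers back to the
    in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "exons": outdir / "exons.bed",
        "peaks": outdir / "peaks.bed",
        "variants": outdir / "variants.vcf",
        "motifs": outdir / "motif.jaspar",
        "truth": outdir / "truth.json",
    }

    with open(paths["genome"], "w") as fh:
        for name, seq in t.genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    with open(paths["exons"], "w") as fh:
        for i, e in enumerate(t.planted_peaks.exons, start=1):
            fh.write(f"{e.seq_name}\t{e.start}\t{e.end}\texon{i}\t0\t{e.strand}\n")

    with open(paths["peaks"], "w") as fh:
        for tf, iv in t.planted_peaks.tf_peaks:
            fh.write(f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{tf}\t0\t{iv.strand}\n")

    with open(paths["variants"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={t.spec.seq_name}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in t.planted_snps:
            fh.write(f"{v.seq_name}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\n")

    write_jaspar_pfm([t.spec.tf_motif], paths["motifs"])

    truth = {
        "seed": t.spec.seed,
        "seq_name": t.spec.seq_name,
        "gene": {
            "name": t.gene_model.gene_name,
            "strand": t.gene_model.strand,
            "exons": [[e.start, e.end] for e in t.gene_model.exons],
        },
        "gene_region": [t.gene_region.start, t.gene_region.end],
        "paralog_region": [t.paralog_region.start, t.paralog_region.end],
        "substitution_positions": t.substitution_positions,
        "snp_positions": [v.pos for v in t.planted_snps],
        "n_tf_peaks": len(t.planted_peaks.tf_peaks),
        "paralog_divergence": t.spec.paralog_divergence,
        "divergence_mode": t.spec.divergence_mode,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
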