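# Methods

## Problem and model

Cas9 binds a 20-nt protospacer immediately 5' of an NGG PAM and tolerates a
small number of sgRNA:DNA mismatches — sites differing by 1–3 bases can be
cleaved at appreciable rates, and PAM-proximal mismatches are only *on
average* more disruptive. For a gene inside a tandem-duplicated cluster this
is the central design hazard: the paralog differs from the target by a few
percent at most, so many guides drawn from the target have near-perfect
matches in the paralog. `sgselect` treats guide design as a screening and
ranking problem over all pattern-matching candidates rather than as a
scoring problem: with no validated weighting scheme to hand, it counts
mismatches uniformly and ranks by interpretable count metrics.

## Conventions

- **Coordinates.** Internal: 0-based half-open on the reference strand.
  External (CLI, reports): 1-based inclusive, `chrom:start-end`. All site
  coordinates are reported on the reference axis with a strand flag;
  protospacer and PAM strings are 5'→3' on the site's own strand.
- **Alphabet.** A/C/G/T/N, upper-cased on input; soft-masking is ignored.
  Candidate windows containing N are skipped. In off-target matching a
  position where either base is N counts as a mismatch (N never matches,
  including N vs N), and windows whose PAM contains N are rejected.
- **Mismatch positions** are numbered 1–20 with 1 at the PAM-distal (5')
  end.

## Candidate enumeration

All 23-nt windows on both strands matching G-N19-NGG. The leading-G
constraint comes from U6-promoter transcription of the sgRNA and applies
*only* to candidates, never to off-target windows (off-targets are genomic
sequences bound by the guide, not expression constructs). Overlapping
candidates are retained. Each candidate gets exactly one compartment —
exon or intron — decided by its protospacer midpoint (footprint offset 11,
which is the same reference position on either strand), so boundary-
straddling sites are classified deterministically. Exons include UTRs.
AT% is computed over the 20-nt protospacer only; the fixed NGG PAM would
otherwise bias composition.

## Off-target search

Exhaustive by construction: the protospacer is split into `max_mm + 1`
contiguous near-equal chunks; by pigeonhole, any window with ≤ max_mm
mismatches contains at least one chunk matched exactly. Every exact chunk
occurrence (string search per sequence and strand) proposes a window
aligned by the chunk's offset, which is then verified in full (PAM check +
Hamming count). Unit and acceptance tests assert set equality against an
independent sliding-window oracle for k = 0..3 on random genomes; the
default budget is 3 mismatches, the range where measurable off-target
cleavage has been reported. The PAM is strict NGG — NAG/NRG tolerance is a
documented open choice, and turning it on would only grow hit counts
monotonically. The candidate's own locus (identical coordinates + strand)
is excluded; a second perfect match elsewhere is reported as a 0-mismatch
hit. "Near-identical at a homolog" means ≤ 1 mismatch with the hit midpoint
inside a named homolog interval.

## Annotation and enrichment

Hits are classified with interval trees into exon / TFBS / ncDNA, mutually
exclusive with precedence exon > tfbs > ncdna, using ≥ 1 bp overlap of the
23-nt footprint (peaks are coarse; midpoint rules under-count). TF overlap
is recorded for *all* hits, including exonic ones, so the enrichment count
is not censored by the precedence rule. Enrichment of TF peaks among one
candidate's hits is an exact one-sided binomial upper tail
P(X ≥ k | n, p₀); the default null fraction p₀ is the TF's merged peak bp
divided by genome bp. "Abnormally enriched" has no canonical statistical
definition in this setting, so the binomial/BH construction is this
package's stated operationalization: across a TF panel, Benjamini–Hochberg
at FDR 0.05 flags enriched TFs.

## Motif screening

JASPAR-format PFMs are parsed with Biopython. Scoring: pseudocount 1 per
cell, column-normalized probabilities, log2 odds against uniform 0.25
background, both strands, hit threshold = 0.8 × maximum attainable score
by default (configurable; 1.0 degenerates to consensus matching). The
built-in consensus elements are the textbook forms CCAAT (CCAAT box),
TATAWAW (TATA box) and GGGCGG (GC box); candidates containing any of them
in their 23-nt sequence are flagged. The bundled NF-YA-like matrix used by
the simulator is synthetic (CCAAT core, weak flanks) — it emulates the
shape of a real CCAAT-binding-factor matrix without pinning a database
version.

## Variant screening

A candidate's variant count is the number of records whose REF span
intersects the full 23-nt footprint, PAM included: a PAM-disrupting SNP
abolishes cleavage, so it must disqualify "no known variant" status.
Multi-nucleotide REF alleles count by their full span; ALT alleles and
allele frequencies are ignored (any known variant counts).

## Selection and ranking

Default criteria: intron compartment required; zero overlapping variants;
25 ≤ AT% ≤ 75 (the documented hazard is >75% AT; the symmetric lower bound
is this package's configurable default since extreme-GC guides are also
reported to underperform); no common regulatory boxes. Passing candidates
are ranked lexicographically by total off-targets, then near-identical
homolog hits, then exonic off-targets, then TFBS off-targets, with genomic
start as the final tie-break — a total, input-order-invariant ordering.
The priority order is this package's convention: genome-wide specificity
first, homolog discrimination second, coding damage third.

## Synthetic locus generator

Layout: left background | gene | 600-bp spacer | paralog | right
background, all drawn from one seeded `numpy` generator in a fixed order
(equal seeds ⇒ byte-identical output). Defaults: 20-kb background, exons
of 142/223/261 bp with introns of 130/850 bp (a compact globin-like
three-exon gene, 1606 bp span), GC 0.5, 20 SNPs uniform over the gene
span, 8 TF peaks. The paralog is the gene sequence with i.i.d.
substitutions; in the default `conservation_biased` mode exonic positions
substitute at 0.3× the intron rate (`paralog_divergence`, default 7%),
emulating purifying selection — this is the mechanism by which exon-derived
guides retain near-identical paralog off-targets while intron-derived
guides escape them, and the property the acceptance suite measures over
≥ 10 seeds at 5–10% divergence. Paralog exon copies are included in the
exon annotation (they are coding sequence). TF peaks are placed over motif
consensus instances written into the background, ±75 bp. A separate helper
plants mutated protospacer copies (0..k substitutions, random strand,
forced N-GG PAM) with a truth table for recovery tests.

What the generator does **not** emulate: indel evolution, recombination,
repeat structure, realistic SNP density gradients, chromatin context, or
genome-scale background (tests run on tens of kb). Passing tests therefore
demonstrate algorithmic correctness and the direction of the
exon/intron contrast, not genome-scale hit counts: absolute off-target
numbers on a 25-kb synthetic genome are far below those on a 3-Gb genome.

## Numerical and degenerate-input choices

Problem sizes in the test and acceptance runs (random genomes of 2–30 kb,
10–12 simulated loci, 20–25 planted sites per trial) were chosen as the
smallest scales at which every property is measured with comfortable
margins; the whole suite runs in seconds. Other fixed choices: regions
shorter than 23 nt yield empty candidate lists (not errors); the
enrichment test is undefined (error) at zero hits and exactly 1.0 at
k = 0; ranking of exact metric ties falls through to genomic start, so
re-ordering the input never changes the output; report files are
byte-deterministic — timestamps, when logged, go to stderr only.

## Known limitations

- No weighted off-target score (MIT/CFD-style), no DNA/RNA-bulge
  off-targets, no on-target activity model: counts only.
- Strict NGG; NAG off-targets are invisible to the search.
- Exon annotation is consumed as given; no transcript-model nuances
  (alternative isoforms, CDS vs UTR distinctions beyond the interval set).
- The enrichment null assumes hits land uniformly at peak-fraction rate,
  ignoring sequence composition bias of the guide itself.
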