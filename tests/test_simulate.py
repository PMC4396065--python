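import json

import numpy as np
import pytest

from sgselect.annotation import read_bed
from sgselect.candidates import assign_labels, scan_candidates
from sgselect.motifs import read_jaspar_pfm
from sgselect.offtargets import find_offtargets
from sgselect.sequence import extract_region, read_fasta
from sgselect.simulate import LocusSpec, generate_locus, plant_offtargets, write_fixture
from sgselect.variants import count_overlapping_snps, read_vcf_minimal

from .conftest import random_seq


class TestGenerateLocus:
    def test_same_seed_byte_identical(self):
        a = generate_locus(LocusSpec(seed=7))
        b = generate_locus(LocusSpec(seed=7))
        assert a.genome.sequences == b.genome.sequences
        assert a.planted_snps == b.planted_snps
        assert a.substitution_positions == b.substitution_positions
        assert [p for p in a.planted_peaks.tf_peaks] == [p for p in b.planted_peaks.tf_peaks]

    def test_different_seed_differs(self):
        a = generate_locus(LocusSpec(seed=7))
        b = generate_locus(LocusSpec(seed=8))
        assert a.genome.sequences != b.genome.sequences

    def test_substitution_positions_match_sequence_diff(self, locus_truth):
        t = locus_truth
        gene = extract_region(t.genome, t.gene_region)
        paralog = extract_region(t.genome, t.paralog_region)
        offset = t.paralog_region.start
        diff = [offset + i for i, (a, b) in enumerate(zip(gene, paralog)) if a != b]
        assert diff == sorted(t.substitution_positions)

    def test_observed_divergence_within_three_binomial_sd(self):
        # conservation-biased: overall rate is a mix of exon and intron rates
        spec = LocusSpec(seed=3, paralog_divergence=0.08)
        t = generate_locus(spec)
        n = spec.gene_length
        n_exon = sum(spec.gene_exon_lengths)
        expected_rate = (
            spec.exon_rate_factor * spec.paralog_divergence * n_exon
            + spec.paralog_divergence * (n - n_exon)
        ) / n
        observed = len(t.substitution_positions) / n
        sd = np.sqrt(expected_rate * (1 - expected_rate) / n)
        assert abs(observed - expected_rate) < 3 * sd

    def test_zero_divergence_gives_perfect_paralog_offtargets(self):
        t = generate_locus(LocusSpec(seed=5, paralog_divergence=0.0, n_snps=0))
        sites = assign_labels(
            scan_candidates(t.genome, t.gene_region, t.gene_model), t.gene_model
        )
        assert sites
        for c in sites[:10]:
            hits = find_offtargets(t.genome, c, 0)
            expected_start = (
                c.site.start - t.gene_region.start + t.paralog_region.start
            )
            assert any(
                h.site.start == expected_start and h.strand == c.strand
                and h.mismatch_count == 0
                for h in hits
            )

    def test_exact_snp_count_inside_gene_span(self):
        t = generate_locus(LocusSpec(seed=9, n_snps=5))
        assert len(t.planted_snps) == 5
        for v in t.planted_snps:
            assert t.gene_region.start < v.pos <= t.gene_region.end
            assert t.genome[v.seq_name][v.pos - 1] == v.ref
            assert v.alt != v.ref

    def test_every_peak_contains_a_motif_instance(self):
        t = generate_locus(LocusSpec(seed=13))
        motif = t.spec.tf_motif.consensus
        assert len(t.planted_peaks.tf_peaks) == t.spec.n_tf_peaks
        for _, iv in t.planted_peaks.tf_peaks:
            assert motif in extract_region(t.genome, iv)

    def test_uniform_mode_and_validation(self):
        generate_locus(LocusSpec(seed=1, divergence_mode="uniform"))
        with pytest.raises(ValueError):
            LocusSpec(divergence_mode="banana")
        with pytest.raises(ValueError):
            LocusSpec(gene_intron_lengths=[100])
        with pytest.raises(ValueError):
            LocusSpec(paralog_divergence=0.5)

    def test_conservation_bias_lowers_exonic_substitution_rate(self):
        exon_subs = intron_subs = 0
        n_exon = n_intron = 0
        for seed in range(8):
            spec = LocusSpec(seed=seed, paralog_divergence=0.1)
            t = generate_locus(spec)
            exonic = set()
            for e in t.gene_model.exons:
                exonic.update(range(e.start, e.end))
            shift = t.paralog_region.start - t.gene_region.start
            for p in t.substitution_positions:
                if (p - shift) in exonic:
                    exon_subs += 1
                else:
                    intron_subs += 1
            n_exon += sum(spec.gene_exon_lengths)
            n_intron += spec.gene_length - sum(spec.gene_exon_lengths)
        assert exon_subs / n_exon < intron_subs / n_intron


class TestPlantOfftargets:
    def test_truth_matches_sequence(self, rng):
        bg = random_seq(rng, 5000)
        proto = "G" + random_seq(rng, 19)
        seq, truth = plant_offtargets(bg, proto, 10, 3, rng)
        assert len(seq) == len(bg) and len(truth) == 10
        from .oracles import rc

        for start, strand, n_sub in truth:
            window = seq[start : start + 23]
            if strand == "-":
                window = rc(window)
            mism = sum(1 for a, b in zip(proto, window[:20]) if a != b)
            assert mism == n_sub <= 3
            assert window[21:] == "GG"

    def test_overfull_background_rejected(self, rng):
        with pytest.raises(ValueError):
            plant_offtargets("A" * 100, "G" * 20, 50, 3, rng)


class TestWriteFixture:
    def test_round_trip_through_package_readers(self, locus_truth, fixture_dir):
        t, paths = locus_truth, fixture_dir
        g = read_fasta(paths["genome"])
        assert g.sequences == t.genome.sequences

        exons = read_bed(paths["exons"])
        assert [(e.start, e.end) for e in exons] == [
            (e.start, e.end) for e in t.planted_peaks.exons
        ]

        peaks = read_bed(paths["peaks"], name_field=3)
        assert [(n, iv.start, iv.end) for n, iv in peaks] == [
            (n, iv.start, iv.end) for n, iv in t.planted_peaks.tf_peaks
        ]

        variants = read_vcf_minimal(paths["variants"])
        assert variants == t.planted_snps

        [pfm] = read_jaspar_pfm(paths["motifs"])
        np.testing.assert_allclose(pfm.counts, t.spec.tf_motif.counts)

        truth = json.loads(paths["truth"].read_text())
        assert truth["substitution_positions"] == sorted(t.substitution_positions)
        assert truth["paralog_region"] == [t.paralog_region.start, t.paralog_region.end]

    def test_empty_peaks_writes_valid_empty_bed(self, tmp_path):
        t = generate_locus(LocusSpec(seed=2, n_tf_peaks=0, n_snps=0))
        paths = write_fixture(t, tmp_path / "f")
        assert read_bed(paths["peaks"], name_field=3) == []
        assert read_vcf_minimal(paths["variants"]) == []

    def test_planted_snps_recovered_by_variant_overlap(self, locus_truth):
        t = locus_truth
        sites = assign_labels(
            scan_candidates(t.genome, t.gene_region, t.gene_model), t.gene_model
        )
        # oracle recount: per-candidate overlap computed by brute force
        for c in sites:
            expected = sum(
                1
                for v in t.planted_snps
                if c.site.start + 1 <= v.pos <= c.site.end
            )
            assert count_overlapping_snps(c, t.planted_snps) == expected
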