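import numpy as np
import pytest

from sgselect.candidates import CandidateSite, at_percent, scan_candidates, assign_labels
from sgselect.offtargets import (
    _pigeonhole_chunks,
    count_mismatches,
    find_offtargets,
    summarize_homolog_similarity,
)
from sgselect.sequence import GeneModel, Genome, GenomicInterval
from sgselect.simulate import plant_offtargets

from .conftest import random_seq
from .oracles import brute_offtargets_oracle, rc

I2_1_PROTO = "GACGAATGATTGCATCAGTG"
I1_1_PROTO = "GGGTGGGAAAATAGACCAAT"


def _candidate(proto, pam="TGG", seq_name="query", start=0, strand="+", label="c"):
    return CandidateSite(
        label=label,
        site=GenomicInterval(seq_name, start, start + 23, strand),
        strand=strand,
        protospacer=proto,
        pam=pam,
        region_class="intron",
        at_percent=at_percent(proto),
    )


def _as_set(hits):
    return {(h.site.seq_name, h.site.start, h.strand, h.mismatch_count) for h in hits}


class TestCountMismatches:
    def test_identical(self):
        assert count_mismatches("A" * 20, "A" * 20) == (0, frozenset())

    def test_single_pam_proximal_mismatch(self):
        count, pos = count_mismatches("A" * 20, "A" * 19 + "T")
        assert (count, pos) == (1, frozenset({20}))

    def test_printed_guides_match_positionwise_oracle(self):
        expected = frozenset(
            i + 1 for i, (a, b) in enumerate(zip(I2_1_PROTO, I1_1_PROTO)) if a != b
        )
        count, pos = count_mismatches(I2_1_PROTO, I1_1_PROTO)
        assert pos == expected and count == len(expected)

    def test_n_counts_as_mismatch_even_vs_n(self):
        assert count_mismatches("N" + "A" * 19, "N" + "A" * 19)[0] == 1
        assert count_mismatches("A" * 20, "N" + "A" * 19)[0] == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_mismatches("A" * 20, "A" * 19)


class TestPigeonholeChunks:
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_partition_reassembles(self, n):
        proto = "GACGAATGATTGCATCAGTG"
        chunks = _pigeonhole_chunks(proto, n)
        assert len(chunks) == n
        assert "".join(c for _, c in chunks) == proto
        assert chunks[0][0] == 0


class TestFindOfftargets:
    def test_on_target_excluded(self):
        seq = I2_1_PROTO + "TGG"
        g = Genome({"chrT": seq})
        c = _candidate(I2_1_PROTO, seq_name="chrT", start=0)
        assert find_offtargets(g, c, 3) == []

    def test_second_perfect_copy_is_zero_mismatch_hit(self):
        site = I2_1_PROTO + "TGG"
        g = Genome({"chrT": site + "ACCA" + site})
        c = _candidate(I2_1_PROTO, seq_name="chrT", start=0)
        hits = find_offtargets(g, c, 3)
        assert _as_set(hits) == {("chrT", 27, "+", 0)}

    def test_nag_pam_not_matched(self):
        g = Genome({"chrT": I2_1_PROTO + "TAG"})
        hits = find_offtargets(g, _candidate(I2_1_PROTO), 3)
        assert hits == []

    def test_pam_with_n_rejected_but_protospacer_n_is_mismatch(self):
        g = Genome({"chrT": I2_1_PROTO + "NGG"})
        assert find_offtargets(g, _candidate(I2_1_PROTO), 3) == []
        g2 = Genome({"chrT": "N" + I2_1_PROTO[1:] + "TGG"})
        hits = find_offtargets(g2, _candidate(I2_1_PROTO), 3)
        assert len(hits) == 1 and hits[0].mismatch_count == 1
        assert hits[0].mismatch_positions == frozenset({1})

    def test_planted_two_mismatch_site_in_background_equals_oracle(self, rng):
        bg = random_seq(rng, 10_000)
        proto = list(I2_1_PROTO)
        proto[4], proto[15] = "T", "A"  # 2 substitutions
        planted = "".join(proto) + "AGG"
        pos = 4321
        seq = bg[:pos] + planted + bg[pos + 23 :]
        g = Genome({"chrT": seq})
        c = _candidate(I2_1_PROTO)
        hits = find_offtargets(g, c, 3)
        expected = brute_offtargets_oracle({"chrT": seq}, I2_1_PROTO, 3)
        assert _as_set(hits) == expected
        assert ("chrT", pos, "+", 2) in _as_set(hits)

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_oracle_equivalence_random_genome(self, k, rng):
        seq = random_seq(rng, 20_000, gc=0.4)
        g = Genome({"chrA": seq, "chrB": random_seq(rng, 5_000)})
        c = _candidate("G" + random_seq(rng, 19))
        got = _as_set(find_offtargets(g, c, k))
        expected = brute_offtargets_oracle(g.sequences, c.protospacer, k)
        assert got == expected

    def test_monotone_in_mismatch_budget(self, rng):
        seq = random_seq(rng, 15_000, gc=0.35)
        g = Genome({"chrT": seq})
        c = _candidate("G" + random_seq(rng, 19), seq_name="chrT", start=0)
        prev = set()
        for k in range(4):
            cur = {(h.site.start, h.strand) for h in find_offtargets(g, c, k)}
            assert prev <= cur
            assert all(h.mismatch_count <= k for h in find_offtargets(g, c, k))
            prev = cur

    def test_planted_recovery_both_strands(self, rng):
        bg = random_seq(rng, 30_000)
        proto = "G" + random_seq(rng, 19)
        seq, truth = plant_offtargets(bg, proto, 20, 3, rng)
        g = Genome({"chrT": seq})
        hits = find_offtargets(g, _candidate(proto), 3)
        found = {(h.site.start, h.strand) for h in hits}
        for start, strand, n_sub in truth:
            assert (start, strand) in found
        assert all(h.mismatch_count <= 3 for h in hits)

    def test_invalid_budget_rejected(self):
        g = Genome({"chrT": "A" * 50})
        with pytest.raises(ValueError):
            find_offtargets(g, _candidate(I2_1_PROTO), 6)


class TestHomologSummary:
    def test_no_hits(self):
        s = summarize_homolog_similarity([], {"HBD": GenomicInterval("c", 0, 100)})
        assert s.n_near_identical_at_homolog == 0 and s.homolog_names == ()

    def test_single_one_mismatch_hit_in_region(self, rng):
        from sgselect.offtargets import OffTargetHit

        hit = OffTargetHit(
            candidate_label="E1-1",
            site=GenomicInterval("c", 40, 63, "+"),
            strand="+",
            matched_sequence="G" * 23,
            mismatch_count=1,
            mismatch_positions=frozenset({5}),
        )
        s = summarize_homolog_similarity([hit], {"HBD": GenomicInterval("c", 0, 100)})
        assert s.n_near_identical_at_homolog == 1
        assert s.homolog_names == ("HBD",)

    def test_counts_match_oracle_recount_on_synthetic_paralog(self, locus_truth):
        sites = assign_labels(
            scan_candidates(
                locus_truth.genome, locus_truth.gene_region, locus_truth.gene_model
            ),
            locus_truth.gene_model,
        )
        region = locus_truth.paralog_region
        homologs = {"PARALOG": region}
        for c in sites[:12]:
            hits = find_offtargets(locus_truth.genome, c, 3)
            summary = summarize_homolog_similarity(hits, homologs)
            expected = sum(
                1
                for h in hits
                if h.mismatch_count <= 1
                and region.start <= h.site.start + 11 < region.end
            )
            assert summary.n_near_identical_at_homolog == expected
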