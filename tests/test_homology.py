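"""Glocal motif alignment, background null, mismatch profile, features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import itrseq as iq
from itrseq.homology import _encode, DEFAULT_PARAMS, UNGAPPED_PARAMS
from conftest import PCSK9
from oracles import (enumerate_alignments_oracle, glocal_oracle,
                     ungapped_oracle)


class Site:
    def __init__(self, contig, start, end):
        self.contig, self.start, self.end = contig, start, end


def embed(motif, left, right, rng):
    flank = lambda n: "".join(rng.choice(list("ACGT"), n))
    return flank(left) + motif + flank(right)


class TestSemiGlobalAlign:
    def test_exact_embedded_motif(self):
        rng = np.random.default_rng(0)
        window = embed(PCSK9, 9, 9, rng)
        r = iq.semi_global_align(PCSK9, window)
        assert (r.mismatches, r.matches) == (0, 22)
        assert r.aligned_window == PCSK9
        assert r.score == 22 * 5

    def test_two_substitutions(self):
        rng = np.random.default_rng(1)
        mutant = "A" + PCSK9[1:3] + "C" + PCSK9[4:]  # subs at positions 1, 4
        window = embed(mutant, 9, 9, rng)
        r = iq.semi_global_align(PCSK9, window, UNGAPPED_PARAMS)
        assert r.mismatches == 2

    def test_poly_a_window_matches_equal_a_count(self):
        """Against a poly-A window every placement matches exactly the
        motif's A positions (3 in the PCSK9 motif)."""
        r = iq.semi_global_align(PCSK9, "A" * 40, UNGAPPED_PARAMS)
        assert r.matches == PCSK9.count("A") == 3
        assert r.mismatches == 19
        # the independent placement oracle agrees
        assert ungapped_oracle(PCSK9, "A" * 40)[1] == 3

    def test_window_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError):
            iq.semi_global_align(PCSK9, "ACGT")

    def test_matches_plus_mismatches_is_motif_length(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = "".join(rng.choice(list("ACGT"), rng.integers(5, 23)))
            w = "".join(rng.choice(list("ACGT"), rng.integers(len(m), 61)))
            for params in (DEFAULT_PARAMS, UNGAPPED_PARAMS):
                r = iq.semi_global_align(m, w, params)
                assert r.matches + r.mismatches == len(m)

    def test_n_bases_never_match(self):
        r = iq.semi_global_align("NNNN", "NNNNNNNN", UNGAPPED_PARAMS)
        assert r.matches == 0


class TestOracleEquivalence:
    def test_dp_equals_recursion_oracle_random_instances(self):
        """The aligner agrees with an independent memoized-recursion
        oracle on 1000 random (motif <= 22, window <= 60) instances."""
        rng = np.random.default_rng(11)
        for i in range(1000):
            m = "".join(rng.choice(list("ACGT"), rng.integers(3, 23)))
            w = "".join(rng.choice(list("ACGT"),
                                   rng.integers(len(m), 61)))
            r = iq.semi_global_align(m, w)
            s, ident = glocal_oracle(m, w)
            assert r.score == pytest.approx(s)
            assert r.matches == ident, (m, w)

    def test_dp_equals_full_enumeration_tiny_instances(self):
        """Literal enumeration of every monotone alignment (tiny cases)
        validates the DP's gap-cost convention end to end."""
        rng = np.random.default_rng(13)
        for _ in range(150):
            m = "".join(rng.choice(list("ACGT"), rng.integers(2, 7)))
            w = "".join(rng.choice(list("ACGT"),
                                   rng.integers(len(m), 13)))
            r = iq.semi_global_align(m, w)
            s, ident = enumerate_alignments_oracle(m, w)
            assert r.score == pytest.approx(s)
            assert r.matches == ident, (m, w)

    def test_ungapped_params_equal_placement_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            m = "".join(rng.choice(list("ACGT"), rng.integers(3, 23)))
            w = "".join(rng.choice(list("ACGT"),
                                   rng.integers(len(m), 61)))
            r = iq.semi_global_align(m, w, UNGAPPED_PARAMS)
            s, ident = ungapped_oracle(m, w)
            assert (r.score, r.matches) == (pytest.approx(s), ident)

    def test_batch_scorer_equals_single_alignments(self):
        rng = np.random.default_rng(19)
        wins = rng.integers(0, 4, size=(200, 40), dtype=np.int8)
        for params in (DEFAULT_PARAMS, UNGAPPED_PARAMS):
            scores, matches = iq.batch_semi_global_scores(PCSK9, wins, params)
            for i in range(0, 200, 7):
                w = "".join("ACGT"[c] for c in wins[i])
                r = iq.semi_global_align(PCSK9, w, params)
                assert (r.score, r.matches) == (scores[i], matches[i])


class TestAnnotateSite:
    @pytest.fixture(scope="class")
    def genome(self):
        rng = np.random.default_rng(23)
        base = "".join(rng.choice(list("ACGT"), 10_000))
        seq = base[:4000] + PCSK9 + base[4000 + 22:7000] + \
            iq.revcomp(PCSK9) + base[7000 + 22:]
        return iq.GenomeRef({"chr1": seq})

    def test_exact_copy_zero_mismatches_plus(self, genome):
        ann = iq.annotate_site_homology(Site("chr1", 4010, 4011), genome,
                                        PCSK9)
        assert (ann.mismatches, ann.motif_orientation) == (0, "+")
        assert ann.predicted_sequence == PCSK9
        assert ann.window_end - ann.window_start >= 40

    def test_reverse_complement_copy_minus(self, genome):
        ann = iq.annotate_site_homology(Site("chr1", 7010, 7011), genome,
                                        PCSK9)
        assert (ann.mismatches, ann.motif_orientation) == (0, "-")
        assert ann.predicted_sequence == PCSK9

    def test_strand_symmetry(self, genome):
        """Annotating the reverse-complemented genome flips the
        orientation but preserves the mismatch count."""
        L = genome.lengths["chr1"]
        rc = iq.GenomeRef({"chr1": iq.revcomp(genome.contigs["chr1"])})
        for start in (4010, 7010, 1500):
            fwd = iq.annotate_site_homology(Site("chr1", start, start + 1),
                                            genome, PCSK9)
            rev = iq.annotate_site_homology(
                Site("chr1", L - start - 1, L - start), rc, PCSK9)
            assert fwd.mismatches == rev.mismatches
            if fwd.mismatches == 0:
                assert fwd.motif_orientation != rev.motif_orientation

    def test_window_truncated_at_contig_end(self):
        g = iq.GenomeRef({"c": PCSK9 + "ACGTACGT"})
        with pytest.warns(UserWarning):
            ann = iq.annotate_site_homology(Site("c", 2, 3), g, PCSK9)
        assert ann.window_start == 0


class TestBackground:
    def test_planted_motif_zero_mean(self):
        g = iq.GenomeRef({"c": (PCSK9 + "ACGTACGTACGTACGTAC") * 50})
        null = iq.random_background(PCSK9, 200, region_len=40, source=g,
                                    seed=1)
        assert null.mean_mismatches <= 6  # every window contains most of a copy

    def test_histogram_mass_conserved(self):
        null = iq.random_background(PCSK9, 500, seed=3)
        assert null.histogram.sum() == 500
        assert 0 <= null.mean_mismatches <= 22

    def test_single_region(self):
        null = iq.random_background(PCSK9, 1, seed=4)
        assert null.histogram.sum() == 1

    def test_deterministic_for_seed(self):
        a = iq.random_background(PCSK9, 300, seed=9)
        b = iq.random_background(PCSK9, 300, seed=9)
        assert np.array_equal(a.histogram, b.histogram)

    def test_mean_stable_across_seeds(self):
        means = [iq.random_background(PCSK9, 4000, seed=s).mean_mismatches
                 for s in (1, 2)]
        assert abs(means[0] - means[1]) < 0.2  # Monte-Carlo error only

    def test_region_len_below_motif_rejected(self):
        with pytest.raises(ValueError):
            iq.random_background(PCSK9, 10, region_len=10)

    def test_genomic_windows_reject_n(self):
        g = iq.GenomeRef({"c": "ACGT" * 30 + "N" * 5 + "TGCA" * 30})
        null = iq.random_background(PCSK9, 50, region_len=40, source=g,
                                    seed=5)
        assert null.histogram.sum() == 50


class TestMismatchProfile:
    def ann(self, seq, mismatches):
        return iq.HomologyAnnotation(
            predicted_sequence=seq, motif_orientation="+",
            matches=len(PCSK9) - mismatches, mismatches=mismatches,
            score=0.0, window_start=0, window_end=40)

    def test_single_perfect_site(self):
        prof = iq.mismatch_profile([self.ann(PCSK9, 0)], PCSK9)
        assert (prof["match"] == 1.0).all()

    def test_read_weighted_fraction(self):
        mutant = PCSK9[:3] + ("A" if PCSK9[3] != "A" else "C") + PCSK9[4:]
        prof = iq.mismatch_profile(
            [self.ann(mutant, 1), self.ann(PCSK9, 0)], PCSK9,
            weights=[9, 1])
        assert prof.loc[4, "mismatch"] == pytest.approx(0.9)
        assert prof.loc[5, "mismatch"] == 0.0
        assert np.allclose(prof.sum(axis=1), 1.0)

    def test_retention_rule_excludes_11_mismatches(self):
        eleven = "".join(
            ("A" if b != "A" else "C") if i < 11 else b
            for i, b in enumerate(PCSK9))
        with pytest.warns(UserWarning):
            prof = iq.mismatch_profile([self.ann(eleven, 11)], PCSK9,
                                       max_mismatches=10)
        assert prof.empty

    def test_wrong_length_prediction_excluded(self):
        with pytest.warns(UserWarning):
            prof = iq.mismatch_profile([self.ann(PCSK9[:20], 2)], PCSK9)
        assert prof.empty


GFF = """\
##gff-version 3
chr1\ttest\tgene\t2001\t6000\t.\t+\t.\tID=gene1;Name=Pcsk9
chr1\ttest\tmRNA\t2001\t6000\t.\t+\t.\tID=tx1;Parent=gene1
chr1\ttest\texon\t2001\t2500\t.\t+\t.\tID=ex1;Parent=tx1
chr1\ttest\texon\t5501\t6000\t.\t+\t.\tID=ex2;Parent=tx1
chr2\ttest\tgene\t9001\t12000\t.\t-\t.\tID=gene2;Name=Alb
chr2\ttest\tmRNA\t9001\t12000\t.\t-\t.\tID=tx2;Parent=gene2
chr2\ttest\texon\t9001\t12000\t.\t-\t.\tID=ex3;Parent=tx2
"""


class TestFeatures:
    @pytest.fixture(scope="class")
    def model(self, tmp_path_factory):
        p = tmp_path_factory.mktemp("gff") / "genes.gff3"
        p.write_text(GFF)
        return iq.load_gene_models(p)

    def test_exon_call(self, model):
        # mid-exon but > tss_window from both transcript ends
        assert iq.annotate_feature(Site("chr1", 5520, 5540), model,
                                   tss_window=100) == ("exon", "Pcsk9")

    def test_intron_call(self, model):
        assert iq.annotate_feature(Site("chr1", 4000, 4010), model,
                                   tss_window=100) == ("intron", "Pcsk9")

    def test_tss_upstream_window(self, model):
        # 300 bp upstream of the + strand transcript start
        assert iq.annotate_feature(Site("chr1", 1700, 1701), model,
                                   tss_window=1000) == ("TSS", "Pcsk9")

    def test_tss_strand_aware_minus(self, model):
        # upstream of a - strand transcript means beyond its right end
        assert iq.annotate_feature(Site("chr2", 12300, 12301), model,
                                   tss_window=1000) == ("TSS", "Alb")

    def test_intergenic_on_empty_contig(self, model):
        assert iq.annotate_feature(Site("chr3", 100, 101), model) == \
            ("intergenic", "")

    def test_precedence_tss_over_exon(self, model):
        # overlapping both the first exon and the TSS window
        call, gene = iq.annotate_feature(Site("chr1", 2050, 2060), model,
                                         tss_window=1000)
        assert call == "TSS" and gene == "Pcsk9"

    def test_bed12_loader(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t2000\t6000\tPcsk9\t0\t+\t2000\t6000\t0\t2\t"
                     "500,500\t0,3500\n")
        model = iq.load_gene_models(p)
        assert iq.annotate_feature(Site("chr1", 5520, 5540), model,
                                   tss_window=100) == ("exon", "Pcsk9")
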