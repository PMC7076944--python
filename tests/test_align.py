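"""Built-in aligner, soft-clip extraction, clip-to-ITR confirmation."""

import numpy as np
import pytest

import itrseq as iq
from itrseq.align import GenomeIndex


def random_genome(seed, lengths):
    rng = np.random.default_rng(seed)
    return iq.GenomeRef({
        name: "".join(rng.choice(list("ACGT"), n))
        for name, n in lengths.items()
    })


@pytest.fixture(scope="module")
def genome():
    return random_genome(7, {"chr1": 12_000, "chr2": 9_000})


@pytest.fixture(scope="module")
def index(genome):
    return GenomeIndex(genome, k=21)


class TestAlignRead:
    def test_exact_substring_full_match(self, genome, index):
        read = genome.contigs["chr1"][5000:5120]
        aln = iq.align_read("r", read, index)
        assert (aln.contig, aln.start, aln.strand) == ("chr1", 5000, "+")
        assert aln.cigar == [("M", 120)]
        assert aln.mapq == 60

    def test_foreign_prefix_soft_clipped(self, genome, index):
        rng = np.random.default_rng(1)
        foreign = "".join(rng.choice(list("ACGT"), 30))
        read = foreign + genome.contigs["chr1"][5000:5120]
        aln = iq.align_read("r", read, index)
        assert aln.cigar == [("S", 30), ("M", 120)]
        assert aln.start == 5000

    def test_reverse_strand_recovered(self, genome, index):
        read = iq.revcomp(genome.contigs["chr2"][3000:3140])
        aln = iq.align_read("r", read, index)
        assert (aln.contig, aln.start, aln.strand) == ("chr2", 3000, "-")
        assert aln.reference_end == 3140

    def test_repeated_sequence_low_mapq(self, genome):
        # the same 120-mer present on both contigs is ambiguous
        seg = genome.contigs["chr1"][2000:2120]
        contigs = dict(genome.contigs)
        contigs["chr2"] = contigs["chr2"][:4000] + seg + contigs["chr2"][4120:]
        dup = iq.GenomeRef(contigs)
        aln = iq.align_read("r", seg, GenomeIndex(dup, k=21))
        assert aln.mapq <= 3

    def test_too_short_unmapped(self, index):
        assert iq.align_read("r", "ACGTACGTACGT", index) is None

    def test_cigar_lengths_sum_to_read(self, genome, index):
        read = "TTTTTTTTTTTTTTTTTTTTTTTTTT" + genome.contigs["chr1"][100:220]
        aln = iq.align_read("r", read, index)
        assert sum(n for op, n in aln.cigar if op in "MSI") == len(read)


class TestSoftclips:
    def mk(self, cigar, seq, strand="+"):
        return iq.Alignment(read_id="r", contig="c", start=100,
                            strand=strand, cigar=cigar, mapq=60, seq=seq)

    def test_left_clip_extracted(self):
        aln = self.mk([("S", 30), ("M", 120)], "A" * 30 + "C" * 120)
        clips = iq.extract_softclips(aln, min_clip_len=15)
        assert len(clips) == 1
        assert clips[0].side == "left" and clips[0].seq == "A" * 30

    def test_fully_matched_no_clip(self):
        assert iq.extract_softclips(self.mk([("M", 150)], "A" * 150)) == []

    def test_below_threshold_dropped(self):
        aln = self.mk([("S", 10), ("M", 140)], "A" * 10 + "C" * 140)
        assert iq.extract_softclips(aln, min_clip_len=15) == []

    def test_minus_strand_clip_in_read_orientation(self):
        # stored seq is reference-oriented; the clip must come back in
        # read orientation
        aln = self.mk([("M", 120), ("S", 30)], "C" * 120 + "AAGG" + "A" * 26,
                      strand="-")
        clips = iq.extract_softclips(aln)
        assert clips[0].side == "right"
        assert clips[0].seq == iq.revcomp("AAGG" + "A" * 26)


class TestClipToItr:
    ITR = ("GATCTGGACCTCTTTGCCCCAGGGGATTACCGGAAGGTTCCAACCGGTTAAGGCCTT"
           "ACGATCGATCGGCTAGCTAGGATCCATGGTACGTAGCTAGCATCGGATC")

    def test_unique_exact_substring_mapq60(self):
        clip = iq.ClipSegment("r", "left", self.ITR[10:40])
        hit = iq.map_clip_to_itr(clip, self.ITR)
        assert hit.itr_start == 10 and hit.mapq == 60
        assert hit.mapq >= 30  # retained by the uniqueness filter

    def test_random_clip_rejected(self):
        rng = np.random.default_rng(3)
        clip = iq.ClipSegment("r", "left", "".join(rng.choice(list("ACGT"), 30)))
        assert iq.map_clip_to_itr(clip, self.ITR) is None

    def test_palindromic_arms_ambiguous(self):
        """A clip present on both arms of a palindromic ITR is rejected.

        Enumerating all placements on a toy two-arm palindrome: the clip
        matches one arm on + and the other arm on -, so exactly two
        co-optimal placements exist and MAPQ <= 3 (< the 30 cut).
        """
        arm = "GGTTACCGGAAGGCCTTAAGGCCGGTTAACC"
        palindrome = arm + "TTTT" + iq.revcomp(arm)
        clip = iq.ClipSegment("r", "left", arm[:20])
        # independent enumeration of perfect placements
        perfect = 0
        for s in (clip.seq, iq.revcomp(clip.seq)):
            for off in range(len(palindrome) - len(clip.seq) + 1):
                perfect += palindrome[off:off + len(clip.seq)] == s
        assert perfect == 2
        hit = iq.map_clip_to_itr(clip, palindrome)
        assert hit.mapq <= 3

    def test_minus_strand_hit(self):
        clip = iq.ClipSegment("r", "left", iq.revcomp(self.ITR[20:50]))
        hit = iq.map_clip_to_itr(clip, self.ITR)
        assert hit.itr_strand == "-" and hit.itr_start == 20


class TestSamRoundTrip:
    def test_export_import_identity(self, genome, index, tmp_path):
        reads = [
            ("a", "TTTTTTTTTTTTTTTTTTTTTTTTT" + genome.contigs["chr1"][500:620]),
            ("b", genome.contigs["chr2"][100:250]),
            ("c", iq.revcomp(genome.contigs["chr1"][9000:9140])),
        ]
        alns = [iq.align_read(rid, s, index, is_read2=True) for rid, s in reads]
        p = tmp_path / "out.sam"
        iq.write_sam(alns, genome, p)
        back = list(iq.import_sam(p, genome))
        for x, y in zip(alns, back):
            assert (x.read_id, x.contig, x.start, x.strand, x.cigar,
                    x.mapq, x.seq, x.is_read2) == \
                   (y.read_id, y.contig, y.start, y.strand, y.cigar,
                    y.mapq, y.seq, y.is_read2)

    def test_hard_clips_dropped_and_ops_merged(self, genome, tmp_path):
        p = tmp_path / "h.sam"
        p.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:12000\n"
            "r\t0\tchr1\t101\t60\t10H50M50M\t*\t0\t0\t" + "A" * 100 +
            "\t*\n"
        )
        aln = next(iq.import_sam(p, genome))
        assert aln.cigar == [("M", 100)]
        assert aln.start == 100

    def test_unknown_contig_rejected(self, genome, tmp_path):
        p = tmp_path / "bad.sam"
        p.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrX\tLN:5000\n"
            "r\t0\tchrX\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"
        )
        with pytest.raises(ValueError):
            list(iq.import_sam(p, genome))
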