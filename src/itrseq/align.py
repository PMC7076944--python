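"""Small-scale read alignment, soft-clip extraction, clip-to-ITR mapping.

The built-in aligner is a k-mer seed-and-extend mapper intended for
desk-scale (kilobase-to-megabase) references: it places a read on the
diagonal suggested by exact seed matches, keeps the best-scoring
contiguous ungapped segment, and reports the unaligned read ends as
soft clips.  Production-scale data aligned with any external mapper can
enter the pipeline through :func:`import_sam` instead; the two routes
produce the same ``Alignment`` records.

MAPQ is a deliberate three-level scheme — 60 for a unique best
placement, 3 for exactly two co-optimal placements, 0 otherwise — since
the only downstream use is the >=30 "unique placement" cut applied to
the clip-to-ITR assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from .refs import GenomeRef, revcomp

__all__ = [
    "Alignment",
    "ClipSegment",
    "ItrHit",
    "GenomeIndex",
    "align_read",
    "extract_softclips",
    "map_clip_to_itr",
    "import_sam",
    "write_sam",
]

# ungapped extension scoring for the seed-and-extend mapper
_SEG_MATCH = 1
_SEG_MISMATCH = -3


@dataclass
class Alignment:
    """One read placement, SAM-style: cigar and seq in reference orientation."""

    read_id: str
    contig: str
    start: int                     # 0-based leftmost aligned reference base
    strand: str                    # "+" or "-"
    cigar: list[tuple[str, int]]   # ops over {M,S,I,D}
    mapq: int
    seq: str = ""                  # reference-oriented read sequence
    is_read2: bool = False

    @property
    def reference_end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.start + sum(n for op, n in self.cigar if op in "MD")

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MSI")


@dataclass
class ClipSegment:
    """A terminal soft-clipped read segment.

    ``side`` is in reference orientation (left = before the alignment
    start); ``seq`` is reported in the original read's orientation.
    """

    read_id: str
    side: str  # "left" or "right"
    seq: str


@dataclass
class ItrHit:
    """Best ungapped placement of a soft clip on the ITR reference."""

    read_id: str
    itr_start: int
    itr_strand: str
    mapq: int
    identity: float


class GenomeIndex:
    """Exact k-mer index over the forward strand of every contig."""

    def __init__(self, genome: GenomeRef, k: int = 21, seed_step: int = 5):
        if k < 1:
            raise ValueError("k must be positive")
        self.genome = genome
        self.k = k
        self.seed_step = seed_step
        self.contig_order = list(genome.contigs)
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.contigs.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if "N" in kmer:
                    continue
                self._kmers.setdefault(kmer, []).append((name, pos))

    def seed_hits(self, seq: str) -> set[tuple[str, int]]:
        """Candidate (contig, diagonal) placements from sampled seeds."""
        out: set[tuple[str, int]] = set()
        positions = list(range(0, len(seq) - self.k + 1, self.seed_step))
        if positions and positions[-1] != len(seq) - self.k:
            positions.append(len(seq) - self.k)
        for off in positions:
            for contig, pos in self._kmers.get(seq[off:off + self.k], ()):
                out.add((contig, pos - off))
        return out


def _best_segment(read: str, ref: str, diag: int) -> tuple[int, int, int]:
    """Best-scoring contiguous ungapped segment of ``read`` at ``diag``.

    Returns (score, read_start, read_end) with end exclusive; positions
    falling outside the contig cannot align and bound the segment.
    """
    lo = max(0, -diag)
    hi = min(len(read), len(ref) - diag)
    best = (0, 0, 0)
    run_score, run_start = 0, lo
    for i in range(lo, hi):
        pt = _SEG_MATCH if (read[i] == ref[diag + i] and read[i] != "N") \
            else _SEG_MISMATCH
        if run_score <= 0:
            run_score, run_start = pt, i
        else:
            run_score += pt
        if run_score > best[0]:
            best = (run_score, run_start, i + 1)
    return best


def align_read(read_id: str, seq: str, index: GenomeIndex,
               is_read2: bool = False) -> Alignment | None:
    """Place a read with the built-in seed-and-extend mapper.

    Both orientations are tried; co-optimal placements across distinct
    (contig, position, strand) determine MAPQ (60/3/0).  Returns None
    for reads shorter than k or without any seeded placement.
    """
    seq = seq.upper()
    if len(seq) < index.k:
        return None
    candidates: dict[tuple[str, int, str], tuple[int, int, int]] = {}
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        for contig, diag in index.seed_hits(oriented):
            ref = index.genome.contigs[contig]
            score, rs, re = _best_segment(oriented, ref, diag)
            if re - rs < index.k:
                continue
            key = (contig, diag + rs, strand)
            if score > candidates.get(key, (-1, 0, 0))[0]:
                candidates[key] = (score, rs, re)
    if not candidates:
        return None
    best_score = max(v[0] for v in candidates.values())
    top = sorted(k for k, v in candidates.items() if v[0] == best_score)
    mapq = 60 if len(top) == 1 else (3 if len(top) == 2 else 0)
    contig, start, strand = top[0]
    score, rs, re = candidates[top[0]]
    oriented = seq if strand == "+" else revcomp(seq)
    cigar: list[tuple[str, int]] = []
    if rs:
        cigar.append(("S", rs))
    cigar.append(("M", re - rs))
    if len(oriented) - re:
        cigar.append(("S", len(oriented) - re))
    return Alignment(read_id=read_id, contig=contig, start=start,
                     strand=strand, cigar=cigar, mapq=mapq, seq=oriented,
                     is_read2=is_read2)


def extract_softclips(aln: Alignment, min_clip_len: int = 15
                      ) -> list[ClipSegment]:
    """Terminal soft clips of length >= ``min_clip_len``.

    Clip sequences are returned in the original read's orientation
    (reverse-complemented back for minus-strand alignments); sides stay
    in reference orientation.
    """
    out: list[ClipSegment] = []
    if not aln.cigar:
        return out
    op, n = aln.cigar[0]
    if op == "S" and n >= min_clip_len:
        seg = aln.seq[:n]
        out.append(ClipSegment(aln.read_id, "left",
                               revcomp(seg) if aln.strand == "-" else seg))
    op, n = aln.cigar[-1]
    if len(aln.cigar) > 1 and op == "S" and n >= min_clip_len:
        seg = aln.seq[len(aln.seq) - n:]
        out.append(ClipSegment(aln.read_id, "right",
                               revcomp(seg) if aln.strand == "-" else seg))
    return out


def map_clip_to_itr(clip: ClipSegment, itr_seq: str,
                    min_identity: float = 0.8) -> ItrHit | None:
    """Exhaustive ungapped scan of a clip against both ITR strands.

    Every placement of the clip on either strand is scored by identity
    (N never matches); the hit reports the best placement with MAPQ 60
    when it is unique, 3 when two placements tie, 0 otherwise — a clip
    landing identically on both arms of a palindromic ITR is therefore
    rejected by the >=30 uniqueness cut.  Returns None when the best
    identity is below ``min_identity``.
    """
    L = len(clip.seq)
    if L == 0 or L > len(itr_seq):
        return None
    itr_seq = itr_seq.upper()
    best_matches = -1
    placements: list[tuple[int, str]] = []
    for strand, oriented in (("+", clip.seq.upper()),
                             ("-", revcomp(clip.seq.upper()))):
        for off in range(len(itr_seq) - L + 1):
            m = sum(1 for a, b in zip(oriented, itr_seq[off:off + L])
                    if a == b and a != "N")
            if m > best_matches:
                best_matches = m
                placements = [(off, strand)]
            elif m == best_matches:
                placements.append((off, strand))
    identity = best_matches / L
    if identity < min_identity:
        return None
    mapq = 60 if len(placements) == 1 else (3 if len(placements) == 2 else 0)
    off, strand = placements[0]
    return ItrHit(clip.read_id, off, strand, mapq, identity)


_OP_FROM_CODE = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}


def _normalize_cigar(cigartuples) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    for code, n in cigartuples:
        if code == 5:  # hard clip: not part of the stored sequence
            continue
        if code not in _OP_FROM_CODE:
            raise ValueError(f"unsupported CIGAR op code {code}")
        op = _OP_FROM_CODE[code]
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))
    return ops


def import_sam(path, genome: GenomeRef):
    """Stream :class:`Alignment` records from a SAM file.

    Lets real-scale data aligned with any external mapper enter the
    pipeline.  Hard clips are dropped and adjacent same-type CIGAR ops
    merged; unmapped records are skipped; a record on a contig absent
    from the genome is an error.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.reference_name not in genome:
                raise ValueError(
                    f"SAM contig {rec.reference_name!r} absent from genome"
                )
            yield Alignment(
                read_id=rec.query_name,
                contig=rec.reference_name,
                start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=_normalize_cigar(rec.cigartuples or []),
                mapq=min(rec.mapping_quality, 60),
                seq=(rec.query_sequence or "").upper(),
                is_read2=rec.is_read2,
            )


def write_sam(alignments, genome: GenomeRef, path) -> None:
    """Export alignments as SAM (the inverse of :func:`import_sam`)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": L} for c, L in genome.lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for aln in alignments:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = aln.read_id
            rec.reference_name = aln.contig
            rec.reference_start = aln.start
            rec.mapping_quality = aln.mapq
            rec.cigarstring = "".join(f"{n}{op}" for op, n in aln.cigar)
            rec.query_sequence = aln.seq
            rec.is_reverse = aln.strand == "-"
            rec.is_read2 = aln.is_read2
            rec.is_paired = aln.is_read2
            fh.write(rec)
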