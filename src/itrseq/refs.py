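"""Reference containers, pipeline configuration, and format I/O.

All genomic coordinates held in memory are 0-based half-open.  The two
record types that describe published loci (:class:`ItrRef`,
:class:`TargetMotif`) accept the 1-based inclusive coordinates that
reports and papers print, and the site report serializer converts back
to that convention; everything in between uses BED/SAM arithmetic.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterator, Sequence

import yaml
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "GenomeRef",
    "ItrRef",
    "TargetMotif",
    "PipelineConfig",
    "SiteReportRow",
    "load_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_site_report",
    "write_sites_bed",
    "revcomp",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMP)[::-1]


class FastaFormatError(ValueError):
    """Raised for malformed or invalid FASTA input."""


class FastqPairingError(ValueError):
    """Raised when R1/R2 files are out of lockstep."""


@dataclass
class GenomeRef:
    """An in-memory reference genome: ordered contig name -> uppercase DNA."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        cleaned: dict[str, str] = {}
        for name, seq in self.contigs.items():
            if not name:
                raise FastaFormatError("empty contig name")
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise FastaFormatError(
                    f"contig {name!r} contains non-DNA characters {sorted(bad)}"
                )
            cleaned[name] = seq
        self.contigs = cleaned

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of ``contig[start:end)``; clipped to the contig bounds."""
        seq = self.contigs[contig]
        return seq[max(0, start):max(0, end)]


@dataclass
class ItrRef:
    """The AAV ITR (or full vector) reference that soft clips are mapped to.

    ``hotspot_position`` is the 1-based coordinate of the most frequent
    integration start site on the ITR (observed at position 82 of the
    AAV2 reference NC_001401.2); ``primer_start`` is the 1-based position
    where the anchored-PCR primer anneals, 5' of the hotspot.  Both are
    metadata: junction calling only needs the sequence.
    """

    name: str
    sequence: str
    hotspot_position: int = 82
    primer_start: int = 1

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not 1 <= self.hotspot_position <= len(self.sequence):
            raise ValueError("hotspot_position outside the ITR sequence")
        if self.primer_start < 1:
            raise ValueError("primer_start must be 1-based positive")

    def expected_prefix(self, primer: str, flank_len: int) -> str:
        """``primer`` plus the next ``flank_len`` ITR bases 3' of its site.

        This is the read-2 prefix the anchored PCR chemistry produces:
        the primer anneals at its site and the amplicon continues through
        the remaining ITR toward the genomic junction.  When
        ``primer_start`` metadata does not point at the primer (e.g. the
        ITR was loaded from a plain FASTA), the unique exact occurrence
        of the primer in the ITR is used instead.
        """
        primer = primer.upper()
        start0 = self.primer_start - 1
        if self.sequence[start0:start0 + len(primer)] != primer:
            hits = [i for i in range(len(self.sequence) - len(primer) + 1)
                    if self.sequence[i:i + len(primer)] == primer]
            if len(hits) != 1:
                raise ValueError(
                    f"primer has {len(hits)} annealing sites on {self.name}; "
                    "set primer_start explicitly"
                )
            start0 = hits[0]
        flank_start = start0 + len(primer)
        flank = self.sequence[flank_start:flank_start + flank_len]
        if len(flank) < flank_len:
            raise ValueError("ITR too short for the requested flank length")
        return primer + flank


@dataclass
class TargetMotif:
    """A nuclease recognition site: motif sequence plus its genomic locus.

    ``start``/``end`` are 1-based inclusive, as printed in reports
    (e.g. the 22-nt PCSK9 site TGGACCTCTTTGCCCCAGGGGA at
    chr1:54708864-54708885).
    """

    sequence: str
    contig: str = ""
    start: int = 0
    end: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("motif sequence must be non-empty")
        if self.contig and (self.end - self.start + 1) != len(self.sequence):
            raise ValueError(
                "motif locus span does not equal motif length "
                f"({self.end}-{self.start}+1 != {len(self.sequence)})"
            )

    @property
    def span0(self) -> tuple[int, int]:
        """The locus as 0-based half-open (start, end)."""
        return self.start - 1, self.end


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults are the assay's published values."""

    max_index_mismatches: int = 1   # demultiplexing, per index
    itr_flank_len: int = 20         # bp of ITR appended to the primer prefix
    max_prefix_mismatches: int = 5  # read-2 prefix selection
    min_clip_len: int = 15          # soft clips shorter than this are ignored
    min_itr_mapq: int = 30          # clip-to-ITR uniqueness filter
    merge_window: int = 50          # bp; junction merge distance
    umi_len: int = 8
    background_region_len: int = 40  # bp; random-region null windows
    kmer: int = 21                  # internal aligner seed length
    min_identity: float = 0.8       # clip-to-ITR minimum identity
    tss_window: int = 1000          # bp around transcript ends for TSS/TTS
    require_mate_concordant: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.type == "int" and v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class SiteReportRow:
    """One line of the final site report (the Dataset-S1-style table)."""

    contig: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    fwd_reads: int
    rev_reads: int
    rank: int
    sample_id: str = ""
    predicted_sequence: str = ""
    motif_orientation: str = ""
    mismatches: int = 0
    feature_class: str = ""
    gene_symbol: str = ""
    is_on_target: bool = False

    @property
    def total_reads(self) -> int:
        return self.fwd_reads + self.rev_reads

    @property
    def location(self) -> str:
        """1-based inclusive span formatted the way the report prints it."""
        return f"{self.contig}:{self.start}–{self.end}"

    def validate(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad interval {self.location}")
        if self.fwd_reads < 1 or self.rev_reads < 1:
            raise ValueError(
                f"site {self.location} fails the bidirectional invariant "
                f"(fwd={self.fwd_reads}, rev={self.rev_reads})"
            )
        if self.rank < 1:
            raise ValueError("rank must be positive")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def load_fasta(path: str | Path) -> GenomeRef:
    """Read a (possibly gzipped) FASTA into a :class:`GenomeRef`.

    Record order is preserved; sequences are uppercased; duplicate
    record names are rejected.
    """
    contigs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in contigs:
                raise FastaFormatError(f"duplicate FASTA record name {rec.id!r}")
            contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise FastaFormatError(f"no FASTA records in {path}")
    return GenomeRef(contigs)


def write_fasta(genome: GenomeRef, path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path
) -> Iterator[tuple[str, str, str, str, str, str]]:
    """Stream lockstep read pairs from two (optionally gzipped) FASTQ files.

    Yields ``(read_id, header1, seq1, qual1, seq2, qual2)`` where
    ``header1`` is the full R1 description line (it carries the barcode
    and UMI tokens).  Raises :class:`FastqPairingError` on unequal record
    counts or mismatched read IDs.
    """
    with _open_text(path_r1) as fh1, _open_text(path_r2) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise FastqPairingError("R1 and R2 have different record counts")
            if rec1.id != rec2.id:
                raise FastqPairingError(
                    f"read ID mismatch: {rec1.id!r} vs {rec2.id!r}"
                )
            q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
            q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
            yield rec1.id, rec1.description, str(rec1.seq), q1, str(rec2.seq), q2


REPORT_COLUMNS = [
    "sample_id", "location", "fwd_reads", "rev_reads", "total_reads",
    "rank", "predicted_sequence", "motif_orientation", "mismatches",
    "feature_class", "gene_symbol", "is_on_target",
]


def write_site_report(rows: Sequence[SiteReportRow], path: str | Path) -> None:
    """Write the TSV site report (1-based inclusive ``contig:start-end``)."""
    for row in rows:
        row.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in (
                r.sample_id, r.location, r.fwd_reads, r.rev_reads,
                r.total_reads, r.rank, r.predicted_sequence,
                r.motif_orientation, r.mismatches, r.feature_class,
                r.gene_symbol, int(r.is_on_target),
            )) + "\n")


def write_sites_bed(rows: Sequence[SiteReportRow], path: str | Path) -> None:
    """Write sites as BED6 (0-based half-open; score = total reads)."""
    for row in rows:
        row.validate()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(v) for v in (
                r.contig, r.start - 1, r.end, f"site_{r.rank}",
                r.total_reads, ".",
            )) + "\n")
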