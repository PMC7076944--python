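"""Genomic feature classification of integration sites.

Sites are classified against a transcript model with the precedence
TSS > TTS > exon > intron > intergenic, where TSS/TTS means the site
lies within a window (default ±1000 bp) of the strand-aware transcript
start/end.  Models load from GFF3 (gene/mRNA/exon) via gffutils or from
BED12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from intervaltree import IntervalTree

__all__ = [
    "Transcript",
    "GeneModel",
    "load_gene_models",
    "annotate_feature",
]

FEATURE_PRECEDENCE = ["TSS", "TTS", "exon", "intron", "intergenic"]


@dataclass
class Transcript:
    """One transcript: 0-based half-open span plus sorted exon blocks."""

    transcript_id: str
    contig: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(
                    f"exon ({s},{e}) outside transcript {self.transcript_id}"
                )
            if s < prev_end and (s, e) != (self.tx_start, prev_end):
                if s < prev_end:
                    raise ValueError(
                        f"overlapping exons in transcript {self.transcript_id}"
                    )
            prev_end = e
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class GeneModel:
    """Transcript collection with per-contig interval indexes."""

    transcripts: dict[str, Transcript]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._trees = {}
        for tx in self.transcripts.values():
            tree = self._trees.setdefault(tx.contig, IntervalTree())
            # include the TSS/TTS flanks in the lookup envelope so a
            # single query finds every transcript that could classify a site
            tree.addi(max(0, tx.tx_start - 100000), tx.tx_end + 100000, tx)

    def overlapping(self, contig: str, start: int, end: int) -> list[Transcript]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda t: (t.tx_start, t.transcript_id))


def _load_gff3(path: str | Path) -> GeneModel:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: dict[str, Transcript] = {}
    for tx in db.features_of_type(("mRNA", "transcript")):
        symbol = ""
        for pid in tx.attributes.get("Parent", []):
            try:
                gene = db[pid]
            except gffutils.FeatureNotFoundError:
                continue
            symbol = gene.attributes.get("Name", [gene.id])[0]
        if not symbol:
            symbol = tx.attributes.get("Name", [tx.id])[0]
        exons = [(e.start - 1, e.end) for e in db.children(tx, featuretype="exon")]
        transcripts[tx.id] = Transcript(
            transcript_id=tx.id,
            contig=tx.seqid,
            strand=tx.strand if tx.strand in "+-" else "+",
            tx_start=tx.start - 1,
            tx_end=tx.end,
            exons=exons or [(tx.start - 1, tx.end)],
            gene_symbol=symbol,
        )
    return GeneModel(transcripts)


def _load_bed12(path: str | Path) -> GeneModel:
    transcripts: dict[str, Transcript] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 line {i + 1} has {len(f)} fields")
            chrom, start, end, name, _score, strand = f[:6]
            start, end = int(start), int(end)
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            tid = name if name not in transcripts else f"{name}.{i}"
            transcripts[tid] = Transcript(
                transcript_id=tid, contig=chrom, strand=strand,
                tx_start=start, tx_end=end, exons=exons, gene_symbol=name,
            )
    return GeneModel(transcripts)


def load_gene_models(path: str | Path) -> GeneModel:
    """Load a transcript model from GFF3 (.gff/.gff3) or BED12 (.bed)."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _load_gff3(path)
    if path.suffix.lower() in {".bed", ".bed12"}:
        return _load_bed12(path)
    raise ValueError(f"unrecognised gene model format: {path.name}")


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def annotate_feature(site, model: GeneModel, tss_window: int = 1000
                     ) -> tuple[str, str]:
    """Classify a site against the transcript model.

    ``site`` needs ``contig``/``start``/``end`` (0-based half-open).
    Returns ``(feature_class, gene_symbol)`` with feature precedence
    TSS > TTS > exon > intron > intergenic; the gene symbol is empty for
    intergenic sites.  TSS and TTS are strand-aware windows of
    ±``tss_window`` bp around the transcript start/end.
    """
    s, e = site.start, site.end
    best = ("intergenic", "")
    best_rank = FEATURE_PRECEDENCE.index("intergenic")
    for tx in model.overlapping(site.contig, s - tss_window, e + tss_window):
        tss = tx.tx_start if tx.strand == "+" else tx.tx_end - 1
        tts = tx.tx_end - 1 if tx.strand == "+" else tx.tx_start
        calls: list[str] = []
        if _overlaps(s, e, tss - tss_window, tss + tss_window + 1):
            calls.append("TSS")
        if _overlaps(s, e, tts - tss_window, tts + tss_window + 1):
            calls.append("TTS")
        if any(_overlaps(s, e, es, ee) for es, ee in tx.exons):
            calls.append("exon")
        elif _overlaps(s, e, tx.tx_start, tx.tx_end):
            calls.append("intron")
        for call in calls:
            rank = FEATURE_PRECEDENCE.index(call)
            if rank < best_rank:
                best, best_rank = (call, tx.gene_symbol), rank
    return best
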