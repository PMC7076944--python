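"""Junction calling, UMI consolidation, site merging/filtering/ranking,
and the end-to-end pipeline.

A junction event is the single reference base adjacent to the
ITR-derived soft clip of a confirmed chimeric read-2 alignment.  Events
are consolidated to unique molecules by UMI, chained into sites by
single-linkage merging within a base-pair window (50 bp by default),
and a site is reported only when it carries junctions in both
integration orientations — the bidirectional filter that suppresses
false positives.  Surviving sites are ranked in decreasing order of
their UMI-consolidated read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from . import align as al
from . import homology as hm
from . import preprocess as pp
from .features import GeneModel, annotate_feature, load_gene_models
from .refs import (
    GenomeRef, ItrRef, PipelineConfig, SiteReportRow, TargetMotif,
    load_fasta, read_fastq_pairs, write_site_report, write_sites_bed,
)

logger = logging.getLogger("itrseq")

__all__ = [
    "JunctionEvent",
    "IntegrationSite",
    "PipelineInputs",
    "PipelineResult",
    "call_junction",
    "consolidate_umis",
    "merge_events",
    "filter_bidirectional",
    "rank_sites",
    "run_pipeline",
]


@dataclass(frozen=True)
class JunctionEvent:
    """One ITR-genome junction observation (possibly a PCR duplicate)."""

    contig: str
    pos: int            # 0-based junction coordinate
    orientation: str    # "+" or "-"
    umi: str
    sample_id: str = ""


@dataclass
class IntegrationSite:
    """A merged integration site with per-orientation molecule counts."""

    contig: str
    start: int  # 0-based half-open envelope of member junction positions
    end: int
    fwd_count: int
    rev_count: int
    sample_id: str = ""
    rank: int = 0
    is_on_target: bool = False
    events: list[JunctionEvent] = field(default_factory=list, repr=False)

    @property
    def total(self) -> int:
        return self.fwd_count + self.rev_count


def call_junction(aln2: al.Alignment, clip: al.ClipSegment, hit: al.ItrHit,
                  min_itr_mapq: int = 30, umi: str = "",
                  sample_id: str = "") -> JunctionEvent | None:
    """Turn an ITR-confirmed chimeric read-2 alignment into an event.

    The junction position is the first aligned reference base adjacent
    to the clipped (ITR) side: the alignment start for a left clip, the
    last aligned base for a right clip.  Orientation is the read-2
    alignment strand.  Hits below the ITR mapping-quality cut (the
    uniqueness filter) produce no event.
    """
    if hit.mapq < min_itr_mapq:
        return None
    pos = aln2.start if clip.side == "left" else aln2.reference_end - 1
    return JunctionEvent(contig=aln2.contig, pos=pos,
                         orientation=aln2.strand, umi=umi,
                         sample_id=sample_id)


def consolidate_umis(events: Iterable[JunctionEvent]) -> list[JunctionEvent]:
    """One event per distinct (sample, contig, pos, orientation, UMI).

    Collapses PCR duplicates to unique molecules; idempotent.  Output is
    sorted, so downstream results do not depend on input order.
    """
    unique = set(events)
    return sorted(unique, key=lambda e: (e.sample_id, e.contig, e.pos,
                                         e.orientation, e.umi))


def merge_events(events: Sequence[JunctionEvent], merge_window: int = 50
                 ) -> list[IntegrationSite]:
    """Single-linkage chaining of consolidated events into sites.

    Per contig (and sample), events sorted by position join the same
    site while the gap to the previous event is at most
    ``merge_window``; the site envelope is [min pos, max pos + 1) and
    per-orientation molecule counts are tallied.
    """
    sites: list[IntegrationSite] = []
    by_group: dict[tuple[str, str], list[JunctionEvent]] = {}
    for ev in events:
        by_group.setdefault((ev.sample_id, ev.contig), []).append(ev)
    for (sample_id, contig), group in sorted(by_group.items()):
        group = sorted(group, key=lambda e: (e.pos, e.orientation, e.umi))
        cluster: list[JunctionEvent] = []
        for ev in group:
            if cluster and ev.pos - cluster[-1].pos > merge_window:
                sites.append(_site_from_cluster(cluster))
                cluster = []
            cluster.append(ev)
        if cluster:
            sites.append(_site_from_cluster(cluster))
    return sites


def _site_from_cluster(cluster: list[JunctionEvent]) -> IntegrationSite:
    return IntegrationSite(
        contig=cluster[0].contig,
        start=min(e.pos for e in cluster),
        end=max(e.pos for e in cluster) + 1,
        fwd_count=sum(1 for e in cluster if e.orientation == "+"),
        rev_count=sum(1 for e in cluster if e.orientation == "-"),
        sample_id=cluster[0].sample_id,
        events=list(cluster),
    )


def filter_bidirectional(sites: Iterable[IntegrationSite]
                         ) -> list[IntegrationSite]:
    """Keep only sites with ITR junctions in both orientations."""
    return [s for s in sites if s.fwd_count >= 1 and s.rev_count >= 1]


def rank_sites(sites: Sequence[IntegrationSite],
               on_target: TargetMotif | None = None,
               merge_window: int = 50,
               contig_order: Sequence[str] | None = None
               ) -> list[IntegrationSite]:
    """Rank sites by decreasing UMI-consolidated read count.

    Ties break by (contig order, start).  When an on-target motif locus
    is given, a site is flagged on-target if its envelope overlaps the
    motif span padded by ``merge_window``.
    """
    order = {c: i for i, c in enumerate(contig_order or [])}
    ranked = sorted(
        sites,
        key=lambda s: (-s.total, order.get(s.contig, 0), s.contig, s.start),
    )
    out = []
    for i, site in enumerate(ranked, start=1):
        flagged = False
        if on_target is not None and on_target.contig == site.contig:
            m0, m1 = on_target.span0
            flagged = (site.start < m1 + merge_window
                       and m0 - merge_window < site.end)
        out.append(replace(site, rank=i, is_on_target=flagged,
                           events=site.events))
    return out


@dataclass
class PipelineInputs:
    """Everything the end-to-end run needs; paths or loaded objects."""

    r1: str | Path
    r2: str | Path
    samples: str | Path
    genome: str | Path | GenomeRef
    itr: str | Path | ItrRef
    primer: str = ""
    motif: TargetMotif | None = None
    genes: str | Path | GeneModel | None = None
    sam: str | Path | None = None


@dataclass
class PipelineResult:
    rows: list[SiteReportRow]
    sites: list[IntegrationSite]
    stage_counts: dict[str, int]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_site_report(self.rows, outdir / "sites.tsv")
        write_sites_bed(self.rows, outdir / "sites.bed")
        with open(outdir / "stage_counts.tsv", "w") as fh:
            fh.write("stage\tcount\n")
            for stage, count in self.stage_counts.items():
                fh.write(f"{stage}\t{count}\n")


def _load_itr(itr: str | Path | ItrRef) -> ItrRef:
    if isinstance(itr, ItrRef):
        return itr
    ref = load_fasta(itr)
    name, seq = next(iter(ref.contigs.items()))
    return ItrRef(name=name, sequence=seq)


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs
                 ) -> PipelineResult:
    """Execute the full assay: demultiplex -> select -> align -> clip ->
    ITR confirmation -> junction call -> UMI consolidation -> merge ->
    bidirectional filter -> rank -> homology/feature annotation.

    Per-stage read-pair counts are returned alongside the report rows;
    the conservation invariant input = selected + prefix-rejected +
    unassigned holds by construction.
    """
    genome = inputs.genome if isinstance(inputs.genome, GenomeRef) \
        else load_fasta(inputs.genome)
    itr = _load_itr(inputs.itr)
    sheet = pp.SampleSheet.from_tsv(inputs.samples)
    if not inputs.primer:
        raise ValueError("the ITR primer sequence is a required input")
    prefix = itr.expected_prefix(inputs.primer, config.itr_flank_len)
    gene_model: GeneModel | None = None
    if inputs.genes is not None:
        gene_model = inputs.genes if isinstance(inputs.genes, GeneModel) \
            else load_gene_models(inputs.genes)

    counts = {
        "input_pairs": 0, "unassigned": 0, "prefix_rejected": 0,
        "selected": 0, "read2_unmapped": 0, "no_usable_clip": 0,
        "clip_not_itr": 0, "itr_mapq_rejected": 0,
        "mate_discordant": 0, "junction_events": 0,
        "consolidated_events": 0, "merged_sites": 0,
        "bidirectional_sites": 0,
    }

    # stage 1-2: demultiplex and prefix-select
    tagged: list[pp.TaggedReadPair] = []
    for read_id, header, seq1, q1, seq2, q2 in read_fastq_pairs(
            inputs.r1, inputs.r2):
        counts["input_pairs"] += 1
        i1, i2, umi = pp.parse_header_tags(header)
        sample = pp.demultiplex(i1, i2, sheet, config.max_index_mismatches)
        if sample is None:
            counts["unassigned"] += 1
            continue
        if not pp.select_itr_reads(seq2, prefix, config.max_prefix_mismatches):
            counts["prefix_rejected"] += 1
            continue
        counts["selected"] += 1
        tagged.append(pp.TaggedReadPair(read_id, sample, umi,
                                        seq1, q1, seq2, q2))

    # stage 3: align read 2 (and mate when concordance is required)
    aln2_by_id: dict[str, al.Alignment] = {}
    if inputs.sam is not None:
        for aln in al.import_sam(inputs.sam, genome):
            if aln.is_read2:
                aln2_by_id[aln.read_id] = aln
        index = None
    else:
        index = al.GenomeIndex(genome, k=config.kmer)

    events: list[JunctionEvent] = []
    clip_cache: dict[str, al.ItrHit | None] = {}
    for pair in tagged:
        if index is not None:
            aln2 = al.align_read(pair.read_id, pair.seq2, index, is_read2=True)
        else:
            aln2 = aln2_by_id.get(pair.read_id)
        if aln2 is None:
            counts["read2_unmapped"] += 1
            continue
        if config.require_mate_concordant and index is not None:
            aln1 = al.align_read(pair.read_id, pair.seq1, index)
            if aln1 is None or aln1.contig != aln2.contig:
                counts["mate_discordant"] += 1
                continue
        clips = al.extract_softclips(aln2, config.min_clip_len)
        if not clips:
            counts["no_usable_clip"] += 1
            continue
        event = None
        for clip in clips:
            cached = clip_cache.get(clip.seq)
            if clip.seq in clip_cache:
                hit = cached
            else:
                hit = al.map_clip_to_itr(clip, itr.sequence,
                                         config.min_identity)
                clip_cache[clip.seq] = hit
            if hit is None:
                continue
            hit = al.ItrHit(clip.read_id, hit.itr_start, hit.itr_strand,
                            hit.mapq, hit.identity)
            if hit.mapq < config.min_itr_mapq:
                counts["itr_mapq_rejected"] += 1
                continue
            event = call_junction(aln2, clip, hit, config.min_itr_mapq,
                                  umi=pair.umi, sample_id=pair.sample_id)
            if event is not None:
                break
        if event is None:
            counts["clip_not_itr"] += 1
            continue
        events.append(event)
    counts["junction_events"] = len(events)

    # stages 4-7: consolidate, merge, filter, rank
    consolidated = consolidate_umis(events)
    counts["consolidated_events"] = len(consolidated)
    merged = merge_events(consolidated, config.merge_window)
    counts["merged_sites"] = len(merged)
    surviving = filter_bidirectional(merged)
    counts["bidirectional_sites"] = len(surviving)

    rows: list[SiteReportRow] = []
    ranked_all: list[IntegrationSite] = []
    for sample_id in sorted({s.sample_id for s in surviving}):
        sample_sites = [s for s in surviving if s.sample_id == sample_id]
        ranked = rank_sites(sample_sites, inputs.motif, config.merge_window,
                            contig_order=list(genome.contigs))
        ranked_all.extend(ranked)
        for site in ranked:
            row = SiteReportRow(
                contig=site.contig, start=site.start + 1, end=site.end,
                fwd_reads=site.fwd_count, rev_reads=site.rev_count,
                rank=site.rank, sample_id=sample_id,
                is_on_target=site.is_on_target,
            )
            if inputs.motif is not None:
                ann = hm.annotate_site_homology(
                    site, genome, inputs.motif.sequence,
                    min_window=max(config.background_region_len,
                                   len(inputs.motif.sequence)),
                )
                row.predicted_sequence = ann.predicted_sequence
                row.motif_orientation = ann.motif_orientation
                row.mismatches = ann.mismatches
            if gene_model is not None:
                row.feature_class, row.gene_symbol = annotate_feature(
                    site, gene_model, config.tss_window)
            rows.append(row)

    for stage, count in counts.items():
        logger.info("stage %s: %d", stage, count)
    return PipelineResult(rows=rows, sites=ranked_all, stage_counts=counts)
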