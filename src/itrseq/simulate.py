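"""Seeded synthetic fixtures: toy genomes, planted ITR integrations, and
anchored-PCR read pairs with ground truth.

The simulator reproduces the observable structure of the assay's
libraries: read 2 of every molecule begins with the ITR primer plus the
downstream ITR flank and continues into the genomic sequence flanking
the integration junction, in either orientation; read 1 is the genomic
mate at a fixed insert; the dual sample indices and the per-molecule
UMI ride in the read header; PCR duplicates share a UMI.  Substitution
errors are applied per read copy.  Everything is deterministic for a
fixed seed, and a ground-truth table of the planted sites and the
read-level manifest come back with the reads so round-trip tests can
compare pipeline output against what was planted.

The bundled "ITR" reference is a random, deliberately non-palindromic
synthetic stand-in for a real vector ITR (whose palindromic arms are a
separate concern, exercised with constructed references in tests); its
hotspot metadata mirrors the observed integration start at position 82.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .refs import GenomeRef, ItrRef, TargetMotif, revcomp, write_fasta, _open_text

logger = logging.getLogger("itrseq")

__all__ = [
    "PlantedSite",
    "TruthTable",
    "Fixture",
    "simulate_genome",
    "simulate_itr",
    "plant_sequence",
    "simulate_reads",
    "default_fixture",
    "write_fixture",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# the printed 22-nt PCSK9 meganuclease recognition site; used as the
# default planted target motif
PCSK9_MOTIF = "TGGACCTCTTTGCCCCAGGGGA"

DEFAULT_SAMPLE = ("S1", "ACGTACGT", "TGCATGCA")


@dataclass
class PlantedSite:
    """Ground truth for one planted integration locus."""

    contig: str
    junction_pos: int          # 0-based junction coordinate
    fwd_depth: int             # unique molecules, "+" orientation
    rev_depth: int             # unique molecules, "-" orientation
    dup_rate: float = 0.0      # expected PCR duplicates per molecule
    label: str = ""
    motif_mismatches: int | None = None  # for planted motif copies

    def __post_init__(self) -> None:
        if self.fwd_depth < 0 or self.rev_depth < 0:
            raise ValueError("depths must be nonnegative")


@dataclass
class TruthTable:
    """Planted sites plus the read-level manifest for round-trip tests."""

    sites: list[PlantedSite]
    genome_seed: int = 0
    # read_id -> (site label, umi, orientation)
    manifest: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def expected_recovered(self) -> list[PlantedSite]:
        """Sites the pipeline must report: >=1 molecule per orientation."""
        return [s for s in self.sites if s.fwd_depth >= 1 and s.rev_depth >= 1]


def simulate_genome(seed: int, n_contigs: int = 2, contig_len: int = 100_000,
                    gc: float = 0.42) -> GenomeRef:
    """A random genome with the requested GC content.

    Contigs are named chr1..chrN.  Deterministic for a fixed seed; for
    contigs of 10 kb and up the realised G+C fraction is within ~2% of
    the target by binomial concentration.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if contig_len < 1000:
        raise ValueError("contig_len must be >= 1 kb")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs = {}
    for i in range(n_contigs):
        draw = rng.choice(BASES, size=contig_len, p=p)
        contigs[f"chr{i + 1}"] = draw.tobytes().decode("ascii")
    return GenomeRef(contigs)


def simulate_itr(seed: int, length: int = 145, primer_len: int = 20,
                 primer_start: int = 42) -> tuple[ItrRef, str]:
    """A synthetic ITR reference plus the primer read off it.

    The primer anneals at ``primer_start`` (1-based) so that primer +
    20 bp flank ends immediately before the integration hotspot
    (position 82 with the defaults), mirroring the real primer placement
    5' of the observed ITR-integration start site.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(BASES, size=length).tobytes().decode("ascii")
    hotspot = primer_start + primer_len + 20
    itr = ItrRef(name="synthetic_itr", sequence=seq,
                 hotspot_position=min(hotspot, length),
                 primer_start=primer_start)
    primer = seq[primer_start - 1:primer_start - 1 + primer_len]
    return itr, primer


def plant_sequence(genome: GenomeRef, contig: str, pos: int, seq: str
                   ) -> GenomeRef:
    """Overwrite genome bases at [pos, pos+len(seq)) with ``seq``."""
    ref = genome.contigs[contig]
    if pos < 0 or pos + len(seq) > len(ref):
        raise ValueError("planted sequence exceeds contig bounds")
    contigs = dict(genome.contigs)
    contigs[contig] = ref[:pos] + seq.upper() + ref[pos + len(seq):]
    return GenomeRef(contigs)


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    """Substitute ``n_mut`` distinct positions with different bases."""
    arr = bytearray(seq.encode())
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        current = chr(arr[pos])
        choices = [b for b in "ACGT" if b != current]
        arr[pos] = ord(choices[rng.integers(0, 3)])
    return arr.decode()


def _apply_errors(seq: str, err_rate: float, rng: np.random.Generator) -> str:
    if err_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < err_rate
    for i in np.nonzero(hit)[0]:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


def _draw_umis(n: int, umi_len: int, rng: np.random.Generator) -> list[str]:
    """``n`` distinct UMIs (collision-free so molecule counts are exact)."""
    space = 4 ** umi_len
    if n > space:
        raise ValueError("more molecules than distinct UMIs")
    codes = rng.choice(space, size=n, replace=False)
    umis = []
    for code in codes:
        umi = ""
        for _ in range(umi_len):
            umi += "ACGT"[code % 4]
            code //= 4
        umis.append(umi)
    return umis


def simulate_reads(
    genome: GenomeRef,
    itr: ItrRef,
    primer: str,
    sites: list[PlantedSite],
    seed: int,
    read_len: int = 150,
    insert: int = 300,
    err_rate: float = 0.0,
    umi_len: int = 8,
    flank_len: int = 20,
    sample: tuple[str, str, str] = DEFAULT_SAMPLE,
) -> tuple[list[tuple[str, str, str]], TruthTable]:
    """Generate anchored-PCR read pairs for the planted sites.

    Returns ``(reads, truth)`` where each read entry is
    ``(header, seq1, seq2)`` — the header carries the ``BC:`` and
    ``UMI:`` tokens — and the truth table maps every read back to its
    source molecule.  Molecules whose junction sits too close to a
    contig edge for the read/insert geometry are skipped with a logged
    warning.
    """
    prefix = itr.expected_prefix(primer, flank_len)
    glen = read_len - len(prefix)
    if glen < 30:
        raise ValueError("read_len must exceed primer + flank by >= 30 bp")
    rng = np.random.default_rng(seed)
    sample_id, i1, i2 = sample

    molecules: list[tuple[PlantedSite, str]] = []
    for site in sites:
        molecules += [(site, "+")] * site.fwd_depth
        molecules += [(site, "-")] * site.rev_depth
    umis = _draw_umis(len(molecules), umi_len, rng)

    reads: list[tuple[str, str, str]] = []
    truth = TruthTable(sites=list(sites), genome_seed=seed)
    for mol_idx, ((site, orient), umi) in enumerate(zip(molecules, umis)):
        ref = genome.contigs[site.contig]
        j = site.junction_pos
        if orient == "+":
            if j < 0 or j + insert > len(ref):
                logger.warning("skipping molecule at %s:%d (+): too close "
                               "to contig edge", site.contig, j)
                continue
            seq2 = prefix + ref[j:j + glen]
            seq1 = revcomp(ref[j + insert - read_len:j + insert])
        else:
            if j - insert + 1 < 0 or j + 1 > len(ref):
                logger.warning("skipping molecule at %s:%d (-): too close "
                               "to contig edge", site.contig, j)
                continue
            seq2 = prefix + revcomp(ref[j - glen + 1:j + 1])
            seq1 = ref[j - insert + 1:j - insert + 1 + read_len]
        n_copies = 1 + (int(rng.poisson(site.dup_rate))
                        if site.dup_rate > 0 else 0)
        for copy in range(n_copies):
            rid = f"mol{mol_idx}d{copy}"
            header = f"{rid} BC:{i1}+{i2} UMI:{umi}"
            reads.append((header,
                          _apply_errors(seq1, err_rate, rng),
                          _apply_errors(seq2, err_rate, rng)))
            truth.manifest[rid] = (site.label, umi, orient)
    rng.shuffle(reads)
    return reads, truth


@dataclass
class Fixture:
    """A complete in-memory test dataset plus its ground truth."""

    genome: GenomeRef
    itr: ItrRef
    primer: str
    motif: TargetMotif
    sites: list[PlantedSite]
    reads: list[tuple[str, str, str]]
    truth: TruthTable
    sample: tuple[str, str, str] = DEFAULT_SAMPLE


def default_fixture(seed: int = 0, err_rate: float = 0.0,
                    read_len: int = 150) -> Fixture:
    """The canonical planted dataset: 2 contigs x 100 kb, one on-target
    site over an exact motif copy, five bidirectional off-target sites
    over motif copies carrying 4-7 substitutions, and one
    forward-only site that the bidirectional filter must drop.

    Unique-molecule depths span 3-50; two sites carry PCR duplicates.
    """
    rng = np.random.default_rng(seed + 1_000_003)
    genome = simulate_genome(seed, n_contigs=2, contig_len=100_000, gc=0.42)
    itr, primer = simulate_itr(seed + 1)
    motif = PCSK9_MOTIF
    half = len(motif) // 2

    plan = [
        # (contig, motif plant pos, n_mut, fwd, rev, dup_rate, label)
        ("chr1", 50_000, 0, 25, 25, 0.0, "on_target"),
        ("chr1", 20_000, 4, 10, 8, 1.0, "off_4mm"),
        ("chr1", 75_000, 5, 5, 3, 0.0, "off_5mm"),
        ("chr2", 30_000, 6, 4, 4, 0.5, "off_6mm"),
        ("chr2", 60_000, 7, 2, 1, 0.0, "off_7mm_a"),
        ("chr2", 85_000, 7, 3, 2, 0.0, "off_7mm_b"),
        ("chr2", 15_000, 6, 4, 0, 0.0, "unidirectional"),
    ]
    sites: list[PlantedSite] = []
    for contig, pos, n_mut, fwd, rev, dup, label in plan:
        planted = motif if n_mut == 0 else _mutate(motif, n_mut, rng)
        genome = plant_sequence(genome, contig, pos, planted)
        sites.append(PlantedSite(
            contig=contig, junction_pos=pos + half, fwd_depth=fwd,
            rev_depth=rev, dup_rate=dup, label=label,
            motif_mismatches=n_mut,
        ))
    target = TargetMotif(sequence=motif, contig="chr1",
                         start=50_001, end=50_000 + len(motif),
                         label="on_target")
    reads, truth = simulate_reads(genome, itr, primer, sites, seed=seed + 2,
                                  read_len=read_len, err_rate=err_rate)
    return Fixture(genome=genome, itr=itr, primer=primer, motif=target,
                   sites=sites, reads=reads, truth=truth)


def write_fixture(fx: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Serialise a fixture to disk: genome.fa, itr.fa, R1/R2.fastq.gz,
    samples.tsv, truth.tsv, manifest.tsv.  Returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "itr": outdir / "itr.fa",
        "r1": outdir / "R1.fastq.gz",
        "r2": outdir / "R2.fastq.gz",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "manifest.tsv",
    }
    write_fasta(fx.genome, paths["genome"])
    write_fasta(GenomeRef({fx.itr.name: fx.itr.sequence}), paths["itr"])
    with _open_text(paths["r1"], "wt") as f1, \
            _open_text(paths["r2"], "wt") as f2:
        for header, seq1, seq2 in fx.reads:
            f1.write(f"@{header}\n{seq1}\n+\n{'I' * len(seq1)}\n")
            f2.write(f"@{header}\n{seq2}\n+\n{'I' * len(seq2)}\n")
    with open(paths["samples"], "w") as fh:
        fh.write("sample_id\tindex1\tindex2\n")
        fh.write("\t".join(fx.sample) + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("label\tcontig\tjunction_pos\tfwd_depth\trev_depth\t"
                 "dup_rate\tmotif_mismatches\n")
        for s in fx.truth.sites:
            fh.write(f"{s.label}\t{s.contig}\t{s.junction_pos}\t"
                     f"{s.fwd_depth}\t{s.rev_depth}\t{s.dup_rate}\t"
                     f"{'' if s.motif_mismatches is None else s.motif_mismatches}\n")
    with open(paths["manifest"], "w") as fh:
        fh.write("read_id\tlabel\tumi\torientation\n")
        for rid, (label, umi, orient) in sorted(fx.truth.manifest.items()):
            fh.write(f"{rid}\t{label}\t{umi}\t{orient}\n")
    return paths
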