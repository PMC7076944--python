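# Methods

## Assay model

An ITR–genome junction library is modelled as a set of *molecules*.
Each molecule arises from one integration event at a junction
coordinate `j` on a contig, in one of two orientations:

* **forward (+)** — the genomic sequence read off the ITR continues
  along the reference plus strand from `j`;
* **reverse (−)** — it continues along the minus strand from `j`.

Orientation is the only observable strand distinction in the read
structure, and the two orientations of one double-stranded break fall
on its two sides; requiring both at a site (the bidirectional filter)
is the assay's principal false-positive control.

Read 2 of a molecule is `[primer][ITR flank][genomic sequence]`, read 1
the genomic mate at a fixed insert; the dual sample indices and the
UMI are carried in the read header as `BC:<i1>+<i2>` and
`UMI:<bases>` tokens (the simulator emulates header-based UMI
extraction; the pipeline consumes the tokens, so UMI chemistry is
decoupled from selection logic). PCR duplicates are extra copies of a
molecule sharing its UMI and coordinates.

## Pipeline stages and thresholds

All internal coordinates are 0-based half-open; conversion to the
1-based inclusive convention used in reports happens only at
serialization (so the printed on-target locus chr1:54708864–54708885
spans exactly the 22 bases of its motif). Defaults, all exposed in
`PipelineConfig` (flat YAML):

| parameter | default | meaning |
|---|---|---|
| `max_index_mismatches` | 1 | per-index Hamming budget in demultiplexing |
| `itr_flank_len` | 20 bp | ITR bases appended to the primer in the read-2 prefix |
| `max_prefix_mismatches` | 5 | Hamming budget for prefix selection |
| `min_clip_len` | 15 bp | shortest soft clip considered ITR-derived |
| `min_itr_mapq` | 30 | clip-to-ITR uniqueness cut |
| `merge_window` | 50 bp | single-linkage junction merge distance |
| `umi_len` | 8 | UMI length |
| `background_region_len` | 40 bp | random-region null window |
| `kmer` | 21 | built-in aligner seed length |
| `min_identity` | 0.8 | clip-to-ITR identity floor |
| `tss_window` | 1000 bp | TSS/TTS flank for feature classes |

Mismatch counting for indices and the prefix is plain Hamming — no
indels — and an `N` in the read always counts as a mismatch. A pair
within the index budget of two samples is unassigned (conservative
standard demultiplexer behaviour).

### Alignment and MAPQ

The built-in mapper is a k-mer seed-and-extend aligner for desk-scale
references: seeds vote for (contig, diagonal, strand) placements, each
candidate is scored by its best contiguous ungapped segment (match +1,
mismatch −3), and unaligned read ends become soft clips. MAPQ is
deliberately three-valued — 60 for a unique best placement, 3 for
exactly two co-optimal, 0 otherwise — because the only downstream use
is the ≥ 30 cut, which therefore means "uniquely placed". Genome-scale
data aligned externally enters through `import_sam` (hard clips
dropped, adjacent CIGAR ops merged); export/import round-trips the
fields the pipeline uses.

Clip-to-ITR confirmation is an exhaustive ungapped scan of every
placement on both ITR strands. Ungapped is intentional: clips are
short primer-anchored ITR fragments, and gap tolerance on a
palindromic reference only adds ambiguity. A clip matching both arms
of a palindromic ITR has two co-optimal placements, scores MAPQ 3, and
is rejected by the uniqueness cut. By default clips are scanned
against the supplied ITR record; supplying the full vector sequence as
that record widens the search space without code changes.

### Junctions, merging, ranking

The junction coordinate is the first aligned reference base adjacent
to the clipped side (alignment start for a left clip, last aligned
base for a right clip). Events are consolidated to one per
(sample, contig, position, orientation, UMI), so "reads" in the report
are unique molecules and duplication cannot inflate ranks. Merging is
single-linkage chaining over sorted positions with gap ≤ 50 bp —
the behaviour of distance-window interval merging — and is therefore
independent of input order and monotone in the window. The
bidirectional rule is evaluated per merged site, not per exact
position, because the two orientations of one break rarely share a
coordinate. Ranks sort by descending consolidated count with ties
broken by (contig order, start); a site is flagged on-target when its
envelope overlaps the motif locus padded by the merge window. The mate
(read 1) is not required to map concordantly by default
(`require_mate_concordant` enables the check).

## Motif homology

`semi_global_align` aligns the target motif globally against a genomic
window whose leading/trailing bases are free (semi-global, "glocal"),
under EMBOSS-style affine scoring (match +5, mismatch −4; a gap of
length L costs `gap_open + L·gap_extend`, defaults 10 and 0.5). It is
implemented as a packed-integer dynamic program — score and identity
count packed into one int64 so a plain maximum is a lexicographic
(score, then identities) maximum — with a vectorised batch form that
scores tens of thousands of windows in seconds. Mismatches are defined
as motif length − aligned identities, so motif bases opposite gaps
count as mismatches and the count is bounded by the motif length.

Site annotation and the random background restrict the search to
**ungapped** placements by default (`UNGAPPED_PARAMS`, a prohibitive
gap-open in the same engine). Two reasons. First, the predicted
nuclease target sequence is by definition a contiguous, motif-length
stretch of genomic DNA — the object the downstream mismatch profile
consumes (which retains only motif-length predictions with ≤ 10
mismatches). Second, this regime reproduces the assay's published
random-region behaviour: 40-bp random DNA averages 11–12 mismatches
against the 22-nt PCSK9 motif over both orientations, which we
measure as 12.00 ± 0.02 at n = 20,000. Under the literal
EMBOSS-default gap costs the score-optimal alignment of dissimilar
sequences stitches matching fragments through affordable internal
gaps, inflating identities (mean mismatches ≈ 9) — a property of the
scoring, verified against two independent oracles (a memoized
recursion and literal enumeration of every monotone alignment on tiny
instances), not of the biology. Gapped alignment remains available by
passing explicit parameters. Orientation ties resolve to "+" for
determinism.

The background null samples uniform-random sequence by default — the
self-contained stand-in for genomic sampling — or random N-free
windows of a supplied genome. Base composition moves the mean only
slightly (GC-biased genomes shift it by ~0.1–0.2 for this motif).

Feature classification uses precedence TSS > TTS > exon > intron >
intergenic, with TSS/TTS as strand-aware ±1 kb windows around the
transcript ends; both the precedence and the window are declared
conventions of this package, matching common annotator practice.

## Statistics

`wilcoxon_signed_rank_exact` computes the exact two-sided signed-rank
p-value for n ≤ 25 pairs by convolving the rank-sum distribution over
all 2ⁿ sign assignments (zero differences dropped; ties share average
ranks; doubled ranks keep all arithmetic in integers). The two-sided
p is P(|W − E[W]| ≥ observed). For n same-signed untied pairs this
gives exactly 2/2ⁿ — 0.03125 at n = 6 — which a normal approximation
cannot produce; the implementation is cross-checked against literal
2ⁿ enumeration and against scipy's exact method on tie-free inputs.

`compare_site_sets` self-merges each interval set, pads every interval
by `slop` (default 50 bp) on both sides, and counts overlap-based
membership in each direction, reporting the percentage of sites
exclusive to the first set.

## Simulator scope

`default_fixture` is the canonical test dataset: 2 contigs × 100 kb at
GC 0.42, a synthetic non-palindromic 145-nt ITR with the primer placed
so that primer + 20-bp flank ends immediately before the integration
hotspot (position 82, mirroring the real primer design), one on-target
site over an exact motif copy, five bidirectional off-target sites over
copies carrying 4–7 substitutions, one forward-only site (exercising
the bidirectional filter), unique-molecule depths 3–50, and PCR
duplicates on two sites. UMIs are drawn without replacement so
molecule counts are exact; reads are shuffled; everything is
deterministic per seed.

The simulator emulates the read *structure*, not platform physics: no
indel errors, flat base qualities, a fixed insert size, and a
non-palindromic ITR stand-in (real-ITR palindromy is exercised with
constructed palindromic references in the tests). Passing round-trip
tests therefore demonstrates the correctness of the selection,
junction, consolidation, merging, filtering and ranking logic — not
robustness to alignment artefacts of real genomes, for which the SAM
import path and an external mapper are intended.

## Problem sizes and numerics

Tests run the full pipeline on the 120-pair default fixture (seconds)
and the oracle-equivalence batteries on 1000 random alignment
instances (motif ≤ 22, window ≤ 60) and 1000 random event sets. The
background null uses 20,000 regions — enough for a Monte-Carlo
standard error of ~0.01 mismatches on the mean. Scores are multiples
of 0.5 and are held as doubled integers throughout, so no
floating-point comparison enters any alignment decision; degenerate
inputs (window shorter than motif, empty event lists, all-zero
differences, reads shorter than the prefix) are either rejected with
a specific error or handled as documented no-ops.

## Known limitations

* The built-in mapper is ungapped and desk-scale; genome-scale or
  indel-containing data should be aligned externally and imported.
* Flip/flop ITR isomers are not modelled; the clip scan treats the
  supplied ITR record as the sole reference.
* Multi-sample joint calling, indel quantification at sites, and
  PAM-/bulge-aware off-target scoring are out of scope.
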