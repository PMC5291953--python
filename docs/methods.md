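# Methods

This note records the models, conventions and numerical choices behind
`isoscope`, in the order the pipeline runs.

## Coordinates and orientation

All intervals are 0-based half-open genomic coordinates, blocks sorted in
ascending genomic order; BED12 is the native interchange and GTF (1-based,
inclusive) is converted on read/write. "5'" and "3'" always mean transcript
orientation: for a minus-strand gene the 5' end is the highest genomic
coordinate. Junction chains list (donor, acceptor) pairs 5'→3' in transcript
orientation.

## Read grammar and extraction

A valid sub-molecule reads as `barcode(16) — Illumina adapter
(AATGATACGGCGACCACCGAT) — UMI(6) — GGG — template — polyA — rc(adapter) —
rc(barcode)` (case 1) or as the exact reverse complement of that layout
(case 2). Case 2 is detected by a ≥10-base T-run adjacent to the forward
adapter and is reverse-complemented before parsing, so the two cases share
one code path and all templates come out in transcript orientation.

Adapter matching is substitution-only (Hamming) with ≤ 2 mismatches,
implemented as a vectorised sliding-window scan. Circular-consensus reads
are substitution-dominated, which keeps the mismatch threshold meaningful;
indel-tolerant matching is deliberately out of scope. Overlapping
self-matches keep the lower-mismatch (tie: leftmost) hit. The sample
barcodes are a fixed panel of eight 16-mers with pairwise Hamming distance
≥ 5, distance ≥ 5 to all 16-windows of the Illumina adapter and to every
reverse complement, so a 2-mismatch match is never ambiguous.

Validity requires one barcode and its reverse complement with no other
barcode between them, each adjacent (±10 bp) to the Illumina adapter, and a
≥10-base A-run abutting the 3' adapter (the poly(A) tail). The UMI is the
6 bases after the forward adapter. The template-switch G-run after the UMI
is trimmed as a maximal run of ≤ 5 G (the protocol writes GGG, but a
template starting with G is indistinguishable from the tail of the run).
Templates containing both an A-run ≥ 10 and a T-run ≥ 10 are dropped as PCR
artifacts. Concatemer records are split between consecutive
(rc(barcode), barcode) matches — the only adjacency the grammar cannot
produce within one molecule — and every sub-interval is parsed
independently; rejection reasons (`no_barcode`, `barcode_conflict`,
`no_adapter`, `no_polya`, `polya_polyt_artifact`, `truncated`) are counted
in the run manifest.

## Alignment ingestion and UMI consensus

The pipeline ingests spliced alignments as BED12 (the simulator emits the
equivalent records directly; real data would come from any spliced
aligner). Names appearing more than once are discarded as non-unique
alignments. Alignment blocks separated by gaps < 40 bp are concatenated
(aligner gap artifacts); 40 bp is a strict upper bound, so a 39 bp gap
merges and a 40 bp gap does not. Reads are assigned to the unique
same-strand gene containing the majority of aligned bases; reads hitting
zero or several genes are excluded. The spike-in ERCC-00074 is excluded
outright: its annotated 3' end is unreliable (two populations of ends in
the original characterisation).

Reads sharing (cell barcode, gene, UMI) collapse into one transcript. The
gene is part of the key because 6-base UMIs (4096 values) collide with
certainty at thousands of molecules per cell; scoping the UMI to a gene
makes collisions rare instead of common. Consensus rules, in order:
identical block lists deduplicate; reads differing only in the extreme 5'
coordinate whose templates share the same first 8 bases after the UMI take
the most 5' position (identical sequence start means the discrepancy is
alignment-induced); otherwise each coordinate takes the group median. The
median of an even-sized group is the lower central value — integral and
deterministic. Groups with discordant exon counts first pick the structure
by majority (ties: more exons, then the longest read's structure) and apply
the median within it; these cases are counted in the manifest.

The conservative transcript set keeps transcripts that have a poly(A) tail
and cover the annotated first exon: the first block must overlap it with
the 5' start not past the exon's 3' edge. Starts inside the first exon are
retained — they are TSS variation, not degradation — while molecules that
lost the entire first exon are excluded.

## Isoform definition

End clusters are built per (gene, side, anchor exon) by single-linkage:
positions linked whenever |a − b| ≤ 5 bp, ranges extending by chaining.
Anchoring on the annotated exon containing the end keeps a truncated
transcript ending in exon 3 from clustering with a full-length end in
exon 1. Single linkage can chain arbitrarily wide clusters; widths are
reported for QC rather than capped.

Full-level isoforms share (gene, 5' cluster, exact junction chain, 3'
cluster). The conservative level applies the 1 bp junction tolerance by
single-linkage clustering of all junction coordinate values pooled across
the gene — one position database per gene, the same rule used for ends.
Pooling matters under realistic jitter: junction values shared by several
exon structures stabilise one another, and a value observed only as J−1 and
J+1 in a sparse context would otherwise split for want of the bridging J. A
plain greedy pairwise merge at ±1 bp was tried first and shatters isoforms
under uniform ±1 jitter (two jittered chains typically differ by 2 bp
somewhere); the clustering formulation recovers the simulated truth.
Values 2 bp apart with no intermediate observation remain distinct, which
preserves the intended boundary behaviour. Each merged isoform is
represented by its best-supported member chain (ties: lexicographically
smallest). Cassette-level isoforms key on the set of annotated exon indices
overlapped, ignoring ends and micro-positions. Transcripts spanning a full
annotated intron (intron retention) are flagged and excluded from event
statistics; they are too rare to classify robustly.

## Statistics

Offset profiles: within each (gene, exon structure) context with ≥ 2
transcripts, offsets are position − lower-median for the 5' end, the 3'
end and every junction coordinate. The same computation runs within UMI
groups (pure technical noise, pre-consensus) and against known ERCC ends
(fractions within ±1 and ±5 bp per side). Sites are labelled coding or
non-coding at the context's median position, so ±1 bp jitter across a CDS
boundary cannot flip individual records; transcript ends labelled coding
are presumed artifacts and excluded from end profiles. Relative end
positions are (pos − TSS)/length along the annotated span, clamped to
[0, 1] for micro-overhangs; 3' ends at rel < 0.15 count as premature
termination.

Event counting builds per-gene databases (end clusters per anchor exon at
5 bp linkage; junction positions at 1 bp linkage) from all transcripts and
maps each cell back onto them: cassette = structures − 1, TSS/TTS = end
clusters observed − 1 summed over anchors, position = junction clusters
observed − 1 summed over (structure, coordinate). The position tolerance
reuses the conservative 1 bp rule so technical jitter does not masquerade
as biology.

Exon co-inclusion uses the two-sided Fisher exact test (scipy) on the 2×2
inclusion table over transcripts whose aligned span covers both exon loci —
absence is unobservable otherwise; tests cross-check scipy against full
hypergeometric enumeration. Coding vs non-coding |offset| comparisons
default to the two-sided rank-sum form because the two site sets are
independent; a signed-rank form pairing per-gene means is also exposed (an
exact null for small tie-free samples, normal approximation otherwise, and
p = 1 for all-zero differences). Isoform sharing across cell types is
computed on one pooled isoform-calling run (keys are only comparable within
a run), restricted to genes with at least one transcript in every cell
type; the major-isoform fraction considers genes with more than 10
transcripts.

## The synthetic data generator

The generator is first-class, tested code and defines the study
conditions. Defaults: 50 genes on one chromosome (4–8 exons of 80–300 bp,
introns 100–500 bp, strand random), CDS excluding 150 bp UTR-like margins
at each transcript end so coding and non-coding junction classes both
occur; 92 single-exon ERCC spike-ins of 255–2007 bp (5% of molecules);
3 cells × 700 molecules; three isoform variants per gene (canonical,
internal cassette exclusion, alternative TSS 20 bp inside the first exon)
at weights 0.5/0.3/0.2; geometric reads-per-UMI with mean 1.6 (≈61%
singletons); 33% of records concatemers of 2–4 molecules; either strand
read with probability 0.5; 70% of endogenous molecules 5'-truncated
(dropping at least the whole first exon, 3' end intact — spike-ins are
never degraded); junction jitter uniform on {−1, 0, 1} and end jitter
uniform on {−4..4} per read, clamped to keep blocks valid. Sequences are
uniform random A/C/G/T fixed by seed; poly(A) is 30 nt (threshold 10, with
margin); quality is a constant Q30 placeholder. A fixed seed yields
byte-identical FASTQ/BED12/GTF/TSV outputs.

What it does not emulate: PacBio's indel-dominated raw error profile and
quality values, chimeras other than end-to-end ligation concatemers,
reverse-transcription artifacts such as strand invasion, internal priming,
3'-side truncation, and non-uniform sequence composition. Passing tests
therefore demonstrate the logic of extraction, consensus and isoform
calling under the modelled noise — not robustness to alignment error or to
base-calling error inside adapters beyond 2 substitutions. Two visible
consequences: the premature-3'-termination fraction is 0 by construction
(no 3' truncation is simulated), and the event-type mix follows the
configured variant kinds rather than any empirical mixture.

## Problem sizes and determinism

Tests and the acceptance script run the generator at desk scale — hundreds
to a few thousand molecules, 8–50 genes — which is ample to exercise every
rule and keeps the whole suite in well under a minute per experiment. All
randomness flows from a single integer seed through one numpy Generator;
the pipeline is deterministic given (config, seed), and the run manifest
records per-stage counts, rejection reasons, a config hash and the package
version so a run can be reproduced and audited.

## Known limitations

One reference structure per gene means unannotated exons are invisible to
cassette keys (blocks overlapping no annotated exon are ignored and
logged). Single-linkage clustering is data-dependent: very deep data can
chain end clusters wide, merging genuinely distinct ends. The 5'-consensus
"first 8 bases" rule assumes the stored template start is informative; with
fewer than 8 template bases it degenerates to the median rule. Barcode
errors are matched, not corrected: a barcode with ≥ 3 substitutions loses
its read.
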