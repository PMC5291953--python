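"""Spliced-alignment ingestion, gene annotation and UMI consensus.

Reads enter as BED12 (one record per subread, blocks = aligned exons).
Alignment blocks less than 40 bp apart are concatenated (aligner gap
artifacts), reads are assigned to the unique gene containing the majority
of their aligned bases, and reads sharing (cell barcode, gene, UMI) are
collapsed into consensus "transcripts".
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .errors import DataError
from .io import Bed12Record
from .types import AlignedRead, Blocks, GeneModel, Transcript, ValidRead

GAP_LT = 40  # blocks closer than this are fused
ERCC_EXCLUDED = {"ERCC-00074"}  # inconsistent annotated 3' end


def merge_close_blocks(blocks: Blocks, gap_lt: int = GAP_LT) -> Blocks:
    """Fuse consecutive blocks whose gap is < gap_lt, to fixpoint."""
    if not blocks:
        return ()
    out = [list(blocks[0])]
    for a, b in blocks[1:]:
        if a - out[-1][1] < gap_lt:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return tuple((a, b) for a, b in out)


def load_alignments(bed_records: list[Bed12Record],
                    valid_reads: dict[str, ValidRead],
                    gap_lt: int = GAP_LT) -> list[AlignedRead]:
    """Join BED12 records with extracted reads; drop multi-mapping names.

    Only uniquely aligned molecules are kept: a read name appearing in more
    than one BED record is discarded entirely.
    """
    names = Counter(r.name for r in bed_records)
    out = []
    for rec in bed_records:
        if names[rec.name] > 1:
            continue
        vr = valid_reads.get(rec.name)
        if vr is None:
            continue
        out.append(AlignedRead(
            read=vr, chrom=rec.chrom, strand=rec.strand,
            blocks=merge_close_blocks(rec.blocks, gap_lt),
            is_ercc=rec.chrom.startswith("ERCC-"),
        ))
    return out


def annotate_genes(reads: list[AlignedRead],
                   models: dict[str, GeneModel]) -> list[AlignedRead]:
    """Assign each read to the unique same-strand gene whose annotated span
    contains the majority of its aligned bases; ambiguous or unmatched reads
    stay unassigned. ERCC reads are assigned to their contig; the excluded
    spike-in (inconsistent reference ends) is left unassigned."""
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models.values():
        by_chrom[m.chrom].append(m)
    for read in reads:
        if read.is_ercc:
            read.gene_id = read.chrom if read.chrom not in ERCC_EXCLUDED else None
            continue
        total = read.aligned_bases
        hits = []
        for m in by_chrom.get(read.chrom, ()):
            if m.strand != read.strand:
                continue
            ga, gb = m.span
            ov = sum(max(0, min(b, gb) - max(a, ga)) for a, b in read.blocks)
            if ov > 0:
                hits.append((m.gene_id, ov))
        majority = [g for g, ov in hits if ov * 2 > total]
        read.gene_id = majority[0] if len(hits) == 1 and len(majority) == 1 else None
    return reads


@dataclass
class UmiMergeLog:
    n_identical: int = 0
    n_most5prime: int = 0
    n_median: int = 0
    n_discordant_structure: int = 0


def _lower_median(values: list[int]) -> int:
    """Median with the even-size convention of taking the lower of the two
    central values (keeps coordinates integral and deterministic)."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def merge_umi_group(reads: list[AlignedRead],
                    log: UmiMergeLog | None = None) -> Transcript:
    """Collapse reads sharing (cell barcode, gene, UMI) into one transcript.

    Rules, in order: (i) identical block lists dedupe to one; (ii) reads
    differing only in their extreme 5' position whose templates share the
    same first 8 bases after the UMI take the most 5' position; (iii)
    otherwise per-coordinate lower-median. Groups with discordant exon
    counts first settle the structure by majority vote (ties: more exons,
    then the structure of the longest read), then apply (iii) within it.
    """
    if not reads:
        raise DataError("empty UMI group")
    log = log if log is not None else UmiMergeLog()
    strand = reads[0].strand
    cell = reads[0].read.barcode
    umi = reads[0].read.umi

    def build(blocks: Blocks, support: int) -> Transcript:
        return Transcript(
            cell_barcode=cell, gene_id=reads[0].gene_id, umi=umi,
            chrom=reads[0].chrom, strand=strand, blocks=blocks,
            read_support=support, has_polya=all(r.read.has_polya for r in reads),
            is_ercc=reads[0].is_ercc,
        )

    block_lists = [r.blocks for r in reads]
    if len(set(block_lists)) == 1:
        log.n_identical += 1
        return build(block_lists[0], len(reads))

    counts = Counter(len(b) for b in block_lists)
    if len(counts) > 1:
        log.n_discordant_structure += 1
        top = max(counts.values())
        cand = [n for n, c in counts.items() if c == top]
        n_blocks = max(cand)
        if len(cand) > 1:
            longest = max(reads, key=lambda r: (r.aligned_bases, len(r.blocks)))
            if len(longest.blocks) in cand:
                n_blocks = len(longest.blocks)
        members = [r for r in reads if len(r.blocks) == n_blocks]
    else:
        members = list(reads)
        n_blocks = len(members[0].blocks)

    blists = [m.blocks for m in members]
    # (ii): identical except the extreme 5' coordinate, same sequence start
    if len(counts) == 1:
        def coords_but_5p(b: Blocks) -> tuple:
            flat = [c for blk in b for c in blk]
            return tuple(flat[1:]) if strand == "+" else tuple(flat[:-1])

        same_rest = len({coords_but_5p(b) for b in blists}) == 1
        first8 = {m.read.first8 for m in members}
        if same_rest and len(first8) == 1:
            log.n_most5prime += 1
            blocks = [list(b) for b in blists[0]]
            if strand == "+":
                blocks[0][0] = min(b[0][0] for b in blists)
            else:
                blocks[-1][1] = max(b[-1][1] for b in blists)
            return build(tuple(tuple(b) for b in blocks), len(reads))

    # (iii): per-coordinate lower median over the winning structure
    log.n_median += 1
    merged = tuple(
        (_lower_median([b[i][0] for b in blists]),
         _lower_median([b[i][1] for b in blists]))
        for i in range(n_blocks)
    )
    return build(merged, len(reads))


def build_transcripts(reads: list[AlignedRead],
                      log: UmiMergeLog | None = None) -> list[Transcript]:
    """Group assigned reads by (cell barcode, gene, UMI) and collapse each
    group. The gene is part of the key to guard against 6-mer UMI collisions
    across genes. Output order is deterministic (sorted keys)."""
    groups: dict[tuple, list[AlignedRead]] = defaultdict(list)
    for r in reads:
        if r.gene_id is None:
            continue
        groups[(r.read.barcode, r.gene_id, r.read.umi)].append(r)
    out = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda r: (r.blocks, r.read.name))
        out.append(merge_umi_group(members, log))
    return out


def covers_first_exon(t: Transcript, model: GeneModel) -> bool:
    """True if the transcript's first block overlaps the annotated first
    exon with its 5' start not past the exon's 3' edge (an upstream start
    still covers the whole exon; within-exon starts are retained as TSS
    variation)."""
    fa, fb = model.first_exon
    if t.strand == "+":
        first = t.blocks[0]
        return first[0] < fb and first[1] > fa
    first = t.blocks[-1]
    return first[1] > fa and first[0] < fb


def filter_full_length(transcripts: list[Transcript],
                       models: dict[str, GeneModel]) -> list[Transcript]:
    """Conservative set: keep transcripts with a poly(A) tail whose blocks
    cover the annotated first exon. Sets covers_first_exon on every input."""
    kept = []
    for t in transcripts:
        model = models.get(t.gene_id)
        if model is None:  # ERCC: single exon, always full by construction
            t.covers_first_exon = True
        else:
            t.covers_first_exon = covers_first_exon(t, model)
        if t.has_polya and t.covers_first_exon:
            kept.append(t)
    return kept
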