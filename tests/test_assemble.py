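"""Alignment ingestion, gene annotation and UMI consensus rules."""
import numpy as np
import pytest

from conftest import make_transcript, noise_free_config, toy_gene
from isoscope.assemble import (
    annotate_genes,
    build_transcripts,
    covers_first_exon,
    filter_full_length,
    load_alignments,
    merge_close_blocks,
    merge_umi_group,
)
from isoscope.errors import DataError
from isoscope.extract import extract_reads
from isoscope.io import blocks_to_bed12
from isoscope.simulate import simulate
from isoscope.types import AlignedRead, ValidRead


@pytest.mark.parametrize("blocks,expected", [
    # gap 39 merges ("less than 40 bp"), gap 40 does not
    (((0, 100), (139, 200)), ((0, 200),)),
    (((0, 100), (140, 200)), ((0, 100), (140, 200))),
    (((0, 100),), ((0, 100),)),
    # cascades to fixpoint
    (((0, 100), (120, 200), (220, 300)), ((0, 300),)),
])
def test_merge_close_blocks(blocks, expected):
    assert merge_close_blocks(blocks) == expected
    # idempotent
    assert merge_close_blocks(expected) == expected


def _vr(name, first8="ACGTACGT"):
    rid, sub = name.split("/")
    return ValidRead(rid, int(sub), "G" * 16, "ACGTCA", 1, first8 + "C" * 50)


def _ar(name, blocks, strand="+", gene="g1", first8="ACGTACGT"):
    r = AlignedRead(read=_vr(name, first8), chrom="chr1", strand=strand,
                    blocks=tuple(blocks))
    r.gene_id = gene
    return r


def test_load_alignments_drops_multimappers():
    beds = [blocks_to_bed12("chr1", "r1/0", "+", ((0, 50),)),
            blocks_to_bed12("chr1", "r1/0", "+", ((100, 150),)),
            blocks_to_bed12("chr1", "r2/0", "+", ((0, 80),))]
    vrs = {"r1/0": _vr("r1/0"), "r2/0": _vr("r2/0")}
    out = load_alignments(beds, vrs)
    assert [a.read.name for a in out] == ["r2/0"]
    assert out[0].blocks == ((0, 80),)


def test_annotate_gene_majority_and_unassigned():
    model = toy_gene()
    reads = [
        AlignedRead(read=_vr("a/0"), chrom="chr1", strand="+",
                    blocks=((120, 200), (300, 380))),
        AlignedRead(read=_vr("b/0"), chrom="chr1", strand="+",
                    blocks=((5000, 5100),)),
        AlignedRead(read=_vr("c/0"), chrom="chr1", strand="-",
                    blocks=((120, 200),)),  # wrong strand
    ]
    annotate_genes(reads, {"g1": model})
    assert reads[0].gene_id == "g1"
    assert reads[1].gene_id is None
    assert reads[2].gene_id is None


def test_merge_identical_reads_dedupes_with_support():
    reads = [_ar("r1/0", ((100, 200), (300, 400))) for _ in range(3)]
    t = merge_umi_group(reads)
    assert t.blocks == ((100, 200), (300, 400))
    assert t.read_support == 3


def test_merge_5prime_rule_takes_most_5prime():
    """Reads identical except the extreme 5' position, sharing the first 8
    template bases, take the most 5' start."""
    reads = [_ar(f"r{i}/0", ((s, 200), (300, 400))) for i, s in
             enumerate((100, 105, 103))]
    t = merge_umi_group(reads)
    assert t.blocks == ((100, 200), (300, 400))
    # minus strand: most 5' is the highest coordinate
    reads = [_ar(f"r{i}/0", ((100, 200), (300, e)), strand="-")
             for i, e in enumerate((395, 400, 398))]
    t = merge_umi_group(reads)
    assert t.blocks == ((100, 200), (300, 400))


def test_merge_5prime_rule_requires_matching_sequence_start():
    """Different first-8 template bases mean a genuinely different 5' end:
    fall back to the median."""
    reads = [_ar(f"r{i}/0", ((s, 200), (300, 400)), first8=f8)
             for i, (s, f8) in enumerate([(100, "AAAATTTT"),
                                          (105, "CCCCGGGG"),
                                          (103, "AAAATTTT")])]
    t = merge_umi_group(reads)
    assert t.blocks == ((103, 200), (300, 400))


def test_merge_median_rule_per_coordinate():
    reads = [_ar(f"r{i}/0", ((100, 200), (300, e)), first8=f8)
             for i, (e, f8) in enumerate([(200 + 200, "AAAAAAAA"),
                                          (202 + 200, "CCCCCCCC"),
                                          (204 + 200, "GGGGGGGG")])]
    t = merge_umi_group(reads)
    assert t.blocks == ((100, 200), (300, 402))


def test_merge_even_group_uses_lower_median():
    reads = [_ar(f"r{i}/0", ((s, 200),), first8=f8)
             for i, (s, f8) in enumerate([(10, "AAAAAAAA"), (12, "CCCCCCCC")])]
    t = merge_umi_group(reads)
    assert t.blocks == ((10, 200),)


def test_merge_discordant_structure_majority_vote():
    reads = [_ar("r0/0", ((100, 200), (300, 400))),
             _ar("r1/0", ((100, 200), (300, 400))),
             _ar("r2/0", ((100, 400),))]
    t = merge_umi_group(reads)
    assert t.blocks == ((100, 200), (300, 400))
    assert t.read_support == 3


def test_merge_permutation_invariant():
    rng = np.random.default_rng(7)
    reads = [_ar(f"r{i}/0", ((100 + i, 200), (300, 400 + i)), first8=f"X{i}" * 4)
             for i in range(5)]
    ref = merge_umi_group(sorted(reads, key=lambda r: r.blocks,),)
    for _ in range(5):
        perm = list(rng.permutation(len(reads)))
        t = merge_umi_group([reads[i] for i in perm])
        assert t.blocks == ref.blocks and t.read_support == ref.read_support


def test_merge_empty_group_errors():
    with pytest.raises(DataError):
        merge_umi_group([])


def test_read_support_conserved_and_umi_collision_guard(clean_sim):
    ex = extract_reads(clean_sim.fastq)
    vrs = {r.name: r for r in ex.valid_reads}
    aligned = load_alignments(clean_sim.alignments, vrs)
    annotate_genes(aligned, {**clean_sim.models, **clean_sim.ercc_models})
    assigned = [r for r in aligned if r.gene_id is not None]
    transcripts = build_transcripts(assigned)
    assert sum(t.read_support for t in transcripts) == len(assigned)
    assert len(transcripts) <= len(assigned)
    # consensus on noise-free input is exact: blocks equal molecule blocks
    mol_by = {}
    for m in clean_sim.molecules:
        mol_by.setdefault((m.barcode, m.gene_id, m.umi), set()).add(m.exon_blocks)
    for t in transcripts:
        key = (t.cell_barcode, t.gene_id, t.umi)
        assert t.blocks in mol_by[key]


def test_ercc_00074_excluded_everywhere(small_sim):
    ex = extract_reads(small_sim.fastq)
    vrs = {r.name: r for r in ex.valid_reads}
    aligned = load_alignments(small_sim.alignments, vrs)
    annotate_genes(aligned, {**small_sim.models, **small_sim.ercc_models})
    assert all(r.gene_id != "ERCC-00074" for r in aligned)
    transcripts = build_transcripts([r for r in aligned if r.gene_id])
    assert all(t.gene_id != "ERCC-00074" for t in transcripts)


def test_covers_first_exon_rules():
    model = toy_gene()  # first exon (100, 200) on +
    full = make_transcript([(100, 200), (300, 400)])
    upstream = make_transcript([(96, 200), (300, 400)])
    within = make_transcript([(150, 200), (300, 400)])
    degraded = make_transcript([(300, 400), (500, 600)])
    assert covers_first_exon(full, model)
    assert covers_first_exon(upstream, model)
    assert covers_first_exon(within, model)  # TSS variation, retained
    assert not covers_first_exon(degraded, model)


def test_filter_full_length_tracks_truth_flags():
    from isoscope.assemble import load_alignments as _load
    res = simulate(noise_free_config(degradation_rate=0.5, ercc_fraction=0.0))
    ex = extract_reads(res.fastq)
    vrs = {r.name: r for r in ex.valid_reads}
    aligned = _load(res.alignments, vrs)
    annotate_genes(aligned, res.models)
    transcripts = build_transcripts([r for r in aligned if r.gene_id])
    kept = filter_full_length(transcripts, res.models)
    truth_full = {}
    for m in res.molecules:
        key = (m.barcode, m.gene_id, m.umi)
        truth_full.setdefault(key, set()).add(m.has_full_first_exon)
    for t in transcripts:
        flags = truth_full[(t.cell_barcode, t.gene_id, t.umi)]
        if len(flags) == 1:  # skip rare UMI collisions mixing both classes
            assert t.covers_first_exon == flags.pop()
    frac = len(kept) / len(transcripts)
    assert abs(frac - 0.5) < 0.06  # binomial fluctuation at this seed
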