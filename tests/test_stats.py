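"""Statistical observables against hand-computed values and brute-force
enumeration oracles."""
import itertools

import numpy as np
import pytest

from _oracles import fisher_exact_two_sided, wilcoxon_exact_two_sided
from conftest import make_transcript, toy_gene
from isoscope import stats as st
from isoscope.types import EventCounts, GeneModel, Isoform, OffsetRecord


# ------------------------------------------------------------- offsets

def test_offset_from_median_examples():
    recs, n_excl = st.offset_from_median({("c",): [10, 12, 14]}, "end5")
    assert sorted(r.offset for r in recs) == [-2, 0, 2]
    recs, _ = st.offset_from_median({("c",): [7, 7, 7]}, "end5")
    assert [r.offset for r in recs] == [0, 0, 0]
    # lower-median convention for even-sized contexts
    recs, _ = st.offset_from_median({("c",): [10, 12]}, "end5")
    assert sorted(r.offset for r in recs) == [0, 2]
    # singleton contexts are excluded and counted
    recs, n_excl = st.offset_from_median({("a",): [5], ("b",): [1, 2]}, "end5")
    assert n_excl == 1 and len(recs) == 2


def test_offset_median_member_property():
    """For an odd-sized context the median member has offset exactly 0 and
    |sum of offsets| <= n."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        vals = list(rng.integers(0, 50, size=int(rng.integers(2, 9))))
        recs, _ = st.offset_from_median({("c",): vals}, "end5")
        offs = [r.offset for r in recs]
        if len(vals) % 2 == 1:
            assert 0 in offs
        assert abs(sum(offs)) <= len(vals) * max(map(abs, offs), default=0)


def test_within_umi_offsets():
    class R:
        def __init__(self, blocks, strand="+"):
            self.blocks = tuple(blocks)
            self.strand = strand

    groups = {("c1", "g1", "u1"): [R([(100, 200)]), R([(100, 200)]),
                                   R([(101, 200)])],
              ("c1", "g1", "u2"): [R([(50, 80)])]}
    recs = st.within_umi_offsets(groups)
    end5 = sorted(r.offset for r in recs if r.site == "end5")
    assert end5 == [0, 0, 1]
    assert all(r.context[:3] == ("c1", "g1", "u1") for r in recs)


def test_ercc_end_offsets_exact_and_unknown_id():
    ercc = {"ERCC-00001": GeneModel("ERCC-00001", "ERCC-00001", "+",
                                    ((0, 500),))}
    exact = make_transcript([(0, 500)], gene_id="ERCC-00001",
                            chrom="ERCC-00001", is_ercc=True)
    recs, frac = st.ercc_end_offsets([exact], ercc)
    assert sorted((r.site, r.offset) for r in recs) == \
        [("end3", 0), ("end5", 0)]
    assert frac[("end5", 1)] == 1.0 and frac[("end3", 5)] == 1.0
    with pytest.raises(Exception):
        st.ercc_end_offsets([make_transcript([(0, 10)], gene_id="nope",
                                             is_ercc=True)], ercc)


def test_ercc_fraction_uniform_pm5():
    """Uniform +-5 end noise: everything within +-5, 3/11 within +-1."""
    ercc = {"E": GeneModel("E", "E", "+", ((10, 1000),))}
    ts = [make_transcript([(10 + d, 1000 + d2)], gene_id="E", chrom="E",
                          is_ercc=True)
          for d in range(-5, 6) for d2 in range(-5, 6)]
    _, frac = st.ercc_end_offsets(ts, ercc)
    assert frac[("end5", 5)] == 1.0
    assert frac[("end3", 5)] == 1.0
    assert frac[("end5", 1)] == pytest.approx(3 / 11)
    assert frac[("end3", 1)] == pytest.approx(3 / 11)


def test_relative_end_positions():
    model = toy_gene()  # span 100..800, length 700, + strand
    at_tts = make_transcript([(100, 200), (700, 800)])
    premature = make_transcript([(100, 170)])  # ends at 10% of span
    overhang = make_transcript([(97, 200), (700, 803)])
    rels, frac = st.relative_end_positions(
        [at_tts, premature, overhang], {"g1": model})
    assert rels[0] == (0.0, 1.0)
    assert rels[1][1] == pytest.approx(0.1) and rels[1][1] < 0.15
    assert rels[2] == (0.0, 1.0)  # micro-overhangs clamp into [0, 1]
    assert frac == pytest.approx(1 / 3)
    minus = GeneModel("g2", "chr1", "-", ((100, 200), (700, 800)))
    rels, _ = st.relative_end_positions(
        [make_transcript([(100, 200), (700, 800)], strand="-", gene_id="g2")],
        {"g2": minus})
    assert rels[0] == (0.0, 1.0)


# ------------------------------------------------------------- events

def _fixture_gene_transcripts():
    """Structures 1-2-3-4 x5 and 1-3-4 x2, two TSS clusters, one TTS
    cluster, one 2 bp junction shift within the 1-3-4 structure."""
    model = toy_gene()
    full = [(100, 200), (300, 400), (500, 600), (700, 800)]
    skip = [(100, 200), (500, 600), (700, 800)]
    skip_shift = [(100, 200), (500, 602), (700, 800)]
    ts = [make_transcript(full) for _ in range(3)]
    ts += [make_transcript([(130, 200)] + full[1:]) for _ in range(2)]  # TSS 2
    ts += [make_transcript(skip)]
    ts += [make_transcript(skip_shift)]
    return model, ts


def test_event_counts_fixture():
    model, ts = _fixture_gene_transcripts()
    counts = st.count_events(ts, {"g1": model})
    assert len(counts) == 1
    c = counts[0]
    assert (c.n_tss, c.n_tts, c.n_cassette, c.n_position) == (1, 0, 1, 1)


def test_event_counts_single_structure_zero_and_increment():
    model = toy_gene()
    full = [(100, 200), (300, 400), (500, 600), (700, 800)]
    ts = [make_transcript(full) for _ in range(4)]
    c = st.count_events(ts, {"g1": model})[0]
    assert (c.n_tss, c.n_tts, c.n_cassette, c.n_position) == (0, 0, 0, 0)
    # one novel structure increments exactly the cassette counter by one
    ts.append(make_transcript([(100, 200), (500, 600), (700, 800)]))
    c = st.count_events(ts, {"g1": model})[0]
    assert (c.n_tss, c.n_tts, c.n_cassette, c.n_position) == (0, 0, 1, 0)


def test_event_position_tolerance_one_bp():
    """+-1 bp junction variants are technical, not position events."""
    model = toy_gene()
    base = [(100, 200), (300, 400)]
    ts = [make_transcript(base), make_transcript([(100, 201), (300, 400)])]
    c = st.count_events(ts, {"g1": model})[0]
    assert c.n_position == 0
    ts.append(make_transcript([(100, 203), (300, 400)]))
    c = st.count_events(ts, {"g1": model})[0]
    assert c.n_position == 1


def test_event_mix_percentages():
    counts = [EventCounts("c", "g", n_tss=3, n_tts=1, n_position=0,
                          n_cassette=1)]
    mix = st.event_mix(counts)
    assert mix["tss"] == pytest.approx(60.0)
    assert sum(mix.values()) == pytest.approx(100.0)


# ------------------------------------------------------------- exact tests

def test_fisher_examples():
    model = toy_gene()
    span = [(100, 200), (700, 800)]
    with_both = make_transcript([(100, 200), (300, 400), (500, 600),
                                 (700, 800)])
    with_neither = make_transcript([(100, 200), (700, 800)])
    ts = [with_both] * 3 + [with_neither] * 3
    p, table = st.exon_connectivity_test(ts, model, 1, 2)
    assert table.tolist() == [[3, 0], [0, 3]]
    assert p == pytest.approx(0.1)
    p, table = st.exon_connectivity_test([], model, 1, 2)
    assert p == 1.0


def test_fisher_matches_enumeration_oracle():
    """scipy's two-sided Fisher p equals full hypergeometric enumeration on
    every 2x2 table with margins <= 10."""
    from scipy.stats import fisher_exact
    for a, b, c, d in itertools.product(range(6), repeat=4):
        table = [[a, b], [c, d]]
        if sum(table[0]) + sum(table[1]) == 0:
            continue
        p_scipy = fisher_exact(table, alternative="two-sided")[1]
        assert p_scipy == pytest.approx(fisher_exact_two_sided(table),
                                        abs=1e-10), table


def test_wilcoxon_matches_sign_enumeration():
    rng = np.random.default_rng(1)
    for _ in range(30):
        n = int(rng.integers(4, 11))
        d = rng.normal(size=n)
        while np.any(d == 0) or len(np.unique(np.abs(d))) < n:
            d = rng.normal(size=n)
        assert st.wilcoxon_signed_rank(d) == \
            pytest.approx(wilcoxon_exact_two_sided(d), abs=1e-12)


def test_wilcoxon_six_pairs_hand_case():
    d = [1.5, -2.0, 3.0, -4.0, 5.0, 6.0]
    assert st.wilcoxon_signed_rank(d) == \
        pytest.approx(wilcoxon_exact_two_sided(d), abs=1e-12)


def test_wilcoxon_degenerate_all_zero():
    assert st.wilcoxon_signed_rank([0.0, 0.0, 0.0]) == 1.0


def test_coding_vs_noncoding_direction():
    """Tight coding sites vs noisy noncoding sites give p < 0.001; identical
    distributions do not."""
    rng = np.random.default_rng(42)
    recs = []
    for i in range(500):
        recs.append(OffsetRecord("junction_start", "coding",
                                 int(rng.integers(-1, 2)), (f"g{i}",)))
        recs.append(OffsetRecord("junction_start", "noncoding",
                                 int(rng.integers(-10, 11)), (f"g{i}",)))
    p = st.coding_vs_noncoding_test(recs, sites=("junction_start",))
    assert p["junction_start"] < 0.001
    same = [OffsetRecord("junction_start", cls, 0, ("g",))
            for cls in ("coding", "noncoding") for _ in range(20)]
    p_same = st.coding_vs_noncoding_test(same, sites=("junction_start",))
    assert p_same["junction_start"] == pytest.approx(1.0)


def test_coding_labels():
    model = toy_gene()  # CDS 160..740 over exons
    assert st.site_is_coding(300, model.cds_intervals)  # junction inside CDS
    assert not st.site_is_coding(120, model.cds_intervals)  # 5' UTR
    assert st.label_coding([300, 120], model.cds_intervals) == [True, False]
    assert st.label_coding([300], ()) == [False]  # gene with no CDS


# ------------------------------------------------------------- sharing

def _iso(gene, key, cells):
    iso = Isoform(gene_id=gene, level="conservative", key=(gene, key),
                  junction_chain=(), cluster_5p=None, cluster_3p=None)
    for i, c in enumerate(cells):
        t = make_transcript([(100, 200)], gene_id=gene, cell=c)
        iso.transcripts.append(t)
        iso.transcript_ids.append(f"{gene}:{key}:{c}:{i}")
    return iso


def test_sharing_example_sets():
    # cell types X, Y, Z observe {A,B}, {B,C}, {B,D}: only B is all-shared
    isos = [_iso("g", "A", ["x1"]), _iso("g", "B", ["x1", "y1", "z1"]),
            _iso("g", "C", ["y1"]), _iso("g", "D", ["z1"])]
    ct = {"x1": "X", "y1": "Y", "z1": "Z"}
    s = st.isoform_sharing(isos, ct)
    assert s.n_isoforms == 4
    assert s.frac_all_shared == pytest.approx(1 / 4)
    assert s.frac_any_two == pytest.approx(1 / 4)
    assert sum(s.venn_counts.values()) == 4
    # identical sets -> everything shared; disjoint genes are filtered out
    isos2 = [_iso("g", "A", ["x1", "y1"]), _iso("g", "B", ["x1", "y1"])]
    s2 = st.isoform_sharing(isos2, {"x1": "X", "y1": "Y"})
    assert s2.frac_all_shared == 1.0
    isos3 = [_iso("g1", "A", ["x1"]), _iso("g2", "B", ["y1"])]
    s3 = st.isoform_sharing(isos3, {"x1": "X", "y1": "Y"})
    assert s3.n_isoforms == 0  # no gene present in all cell types


def test_sharing_invariant_under_relabelling():
    isos = [_iso("g", "A", ["x1", "y1"]), _iso("g", "B", ["x1"]),
            _iso("g", "C", ["y1"])]
    s1 = st.isoform_sharing(isos, {"x1": "X", "y1": "Y"})
    s2 = st.isoform_sharing(isos, {"x1": "Y", "y1": "X"})
    assert s1.frac_any_two == s2.frac_any_two
    assert s1.frac_all_shared == s2.frac_all_shared
    assert sorted(s1.venn_counts.values()) == sorted(s2.venn_counts.values())
    with pytest.raises(Exception):
        st.isoform_sharing(isos, {"x1": "X", "y1": "X"})


def test_major_isoform_fraction():
    isos = [_iso("g", "A", [f"c{i}" for i in range(6)]),
            _iso("g", "B", [f"c{i}" for i in range(3)]),
            _iso("g", "C", [f"c{i}" for i in range(3)])]
    assert st.major_isoform_fraction(isos) == {"g": pytest.approx(0.5)}
    solo = [_iso("g2", "A", [f"c{i}" for i in range(11)])]
    assert st.major_isoform_fraction(solo) == {"g2": 1.0}
    few = [_iso("g3", "A", [f"c{i}" for i in range(10)])]
    assert st.major_isoform_fraction(few) == {}  # needs more than 10


def test_offset_histogram_bins():
    hist = st.offset_histogram([0, 0, 1, -1, 3, -7, 50, -200, 101])
    assert hist["0"] == 2 and hist["+1"] == 1 and hist["-1"] == 1
    assert hist["+2..+5"] == 1 and hist["-10..-6"] == 1
    assert hist["+11..+100"] == 1 and hist["<-100"] == 1 and hist[">+100"] == 1
    assert sum(hist.values()) == 9
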