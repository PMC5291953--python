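"""Statistical observables of isoform diversity.

Offset-from-median profiles (per gene and exon structure, per UMI group,
and against known ERCC ends), relative end positions, isoform event
classification (TSS / TTS / exon position / exon cassette), pairwise exon
connectivity (Fisher's exact test), coding vs non-coding junction
variability (Wilcoxon tests), isoform sharing between cell types, and the
major-isoform expression fraction.
"""
from __future__ import annotations

from collections import Counter, OrderedDict, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DataError
from .isoforms import _anchor_exon, build_end_clusters, has_intron_retention
from .types import (
    Blocks,
    EventCounts,
    GeneModel,
    Isoform,
    OffsetRecord,
    Transcript,
)

PREMATURE_REL3 = 0.15  # 3' ends within the first 15% of gene length
POSITION_TOL = 1  # +-1 bp variants are technical, not position events


def lower_median(values: Sequence[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


# ------------------------------------------------------- offset profiles

def offset_from_median(contexts: Mapping[tuple, Sequence[int]], site: str,
                       coding_of: Mapping[tuple, str] | None = None,
                       ) -> tuple[list[OffsetRecord], int]:
    """Offsets = position - lower-median, per context of >= 2 members.

    Returns (records, n_singleton_contexts_excluded).
    """
    records: list[OffsetRecord] = []
    n_singleton = 0
    for key in sorted(contexts):
        positions = contexts[key]
        if len(positions) < 2:
            n_singleton += 1
            continue
        med = lower_median(positions)
        coding = coding_of.get(key, "na") if coding_of else "na"
        for p in positions:
            records.append(OffsetRecord(site=site, coding=coding,
                                        offset=int(p - med), context=key))
    return records, n_singleton


def site_is_coding(pos: int, cds_intervals: Blocks) -> bool:
    """A site is coding iff it lies within a coding interval of its gene
    (interval ends inclusive: junction coordinates sit on block edges)."""
    return any(a <= pos <= b for a, b in cds_intervals)


def label_coding(positions: Iterable[int], cds_intervals: Blocks) -> list[bool]:
    return [site_is_coding(p, cds_intervals) for p in positions]


def _structure_key(t: Transcript, model: GeneModel | None) -> tuple:
    structure = (tuple(sorted(model.overlapped_exons(t.blocks)))
                 if model else (0,))
    return (t.gene_id, structure, len(t.blocks))


def structure_offsets(transcripts: list[Transcript],
                      models: Mapping[str, GeneModel],
                      coding_by_gene: Mapping[str, Blocks] | None = None,
                      exclude_coding_ends: bool = True,
                      ) -> list[OffsetRecord]:
    """Offset-from-median records per (gene, exon structure) context for 5'
    and 3' ends and every junction donor/acceptor coordinate.

    Sites are labelled coding/non-coding against the gene's CDS intervals
    when provided; transcript ends that label as coding are presumed
    artifacts and excluded from the end profiles.
    """
    groups: dict[tuple, list[Transcript]] = defaultdict(list)
    for t in transcripts:
        if t.is_ercc:
            continue
        groups[_structure_key(t, models.get(t.gene_id))].append(t)
    records: list[OffsetRecord] = []
    for key in sorted(groups):
        members = groups[key]
        if len(members) < 2:
            continue
        gene = key[0]
        cds = coding_by_gene.get(gene, ()) if coding_by_gene else ()

        def emit(site, positions, ctx):
            med = lower_median(positions)
            # the site's class is decided at its consensus location, so +-1
            # jitter across a CDS boundary cannot flip individual records
            coding = ("na" if not cds else
                      ("coding" if site_is_coding(med, cds) else "noncoding"))
            if exclude_coding_ends and site in ("end5", "end3") \
                    and coding == "coding":
                return
            records.extend(
                OffsetRecord(site=site, coding=coding, offset=int(p - med),
                             context=ctx)
                for p in positions)

        emit("end5", [t.end5 for t in members], key + ("end5",))
        emit("end3", [t.end3 for t in members], key + ("end3",))
        n_coords = 2 * (key[2] - 1)
        for i in range(n_coords):
            site = "junction_start" if i % 2 == 0 else "junction_end"
            emit(site, [t.junction_chain()[i] for t in members],
                 key + ("junction", i))
    return records


def within_umi_offsets(groups: Mapping[tuple, list],
                       ) -> list[OffsetRecord]:
    """Same computation with the raw reads of one UMI as the context,
    before consensus (a QC view of pure technical noise). Reads with the
    modal block count carry the junction contexts."""
    records: list[OffsetRecord] = []
    for key in sorted(groups):
        reads = groups[key]
        if len(reads) < 2:
            continue
        counts = Counter(len(r.blocks) for r in reads)
        n_blocks = counts.most_common(1)[0][0]
        members = [r for r in reads if len(r.blocks) == n_blocks]
        strand = members[0].strand

        def chain(r):
            if len(r.blocks) == 1:
                return ()
            pairs = []
            idx = (range(len(r.blocks) - 1) if strand == "+"
                   else range(len(r.blocks) - 1, 0, -1))
            if strand == "+":
                for i in idx:
                    pairs.extend((r.blocks[i][1], r.blocks[i + 1][0]))
            else:
                for i in idx:
                    pairs.extend((r.blocks[i][0], r.blocks[i - 1][1]))
            return tuple(pairs)

        end5s = [r.blocks[0][0] if strand == "+" else r.blocks[-1][1]
                 for r in members]
        end3s = [r.blocks[-1][1] if strand == "+" else r.blocks[0][0]
                 for r in members]
        for site, vals in (("end5", end5s), ("end3", end3s)):
            if len(vals) >= 2:
                med = lower_median(vals)
                records.extend(
                    OffsetRecord(site=site, coding="na", offset=int(p - med),
                                 context=key + (site,))
                    for p in vals)
        if n_blocks > 1 and len(members) >= 2:
            chains = [chain(r) for r in members]
            for i in range(2 * (n_blocks - 1)):
                site = "junction_start" if i % 2 == 0 else "junction_end"
                vals = [c[i] for c in chains]
                med = lower_median(vals)
                records.extend(
                    OffsetRecord(site=site, coding="na", offset=int(p - med),
                                 context=key + ("junction", i))
                    for p in vals)
    return records


# ------------------------------------------------------- ERCC end accuracy

def ercc_end_offsets(transcripts: list[Transcript],
                     ercc_models: Mapping[str, GeneModel],
                     ks: tuple[int, ...] = (1, 5),
                     ) -> tuple[list[OffsetRecord], dict]:
    """Signed offsets of ERCC transcript ends from the known spike-in ends,
    plus the fraction within +-k bp for each k (per side)."""
    records = []
    for t in transcripts:
        if not t.is_ercc:
            continue
        model = ercc_models.get(t.gene_id)
        if model is None:
            raise DataError(f"unknown ERCC id {t.gene_id}")
        known5, known3 = model.exons[0]
        records.append(OffsetRecord(site="end5", coding="na",
                                    offset=int(t.end5 - known5),
                                    context=(t.gene_id,)))
        records.append(OffsetRecord(site="end3", coding="na",
                                    offset=int(t.end3 - known3),
                                    context=(t.gene_id,)))
    fractions = {}
    for side in ("end5", "end3"):
        offs = [r.offset for r in records if r.site == side]
        for k in ks:
            fractions[(side, k)] = (
                float(np.mean([abs(o) <= k for o in offs])) if offs else float("nan"))
    return records, fractions


# ------------------------------------------------------- end positions

def relative_end_positions(transcripts: list[Transcript],
                           models: Mapping[str, GeneModel],
                           premature_threshold: float = PREMATURE_REL3,
                           ) -> tuple[list[tuple[float, float]], float]:
    """Per-transcript (rel5, rel3) in [0, 1] along the annotated TSS->TTS
    span, strand-aware; ends micro-overhanging the annotation are clamped.
    Returns the list plus the premature-termination fraction
    (rel3 < premature_threshold)."""
    rels = []
    for t in transcripts:
        model = models.get(t.gene_id)
        if model is None:
            continue
        length = model.length
        if length <= 0:
            raise DataError(f"zero-length gene {t.gene_id}")
        sign = 1 if model.strand == "+" else -1
        rel5 = sign * (t.end5 - model.annotated_tss) / length
        rel3 = sign * (t.end3 - model.annotated_tss) / length
        rels.append((min(max(rel5, 0.0), 1.0), min(max(rel3, 0.0), 1.0)))
    premature = (float(np.mean([r3 < premature_threshold for _, r3 in rels]))
                 if rels else float("nan"))
    return rels, premature


# ------------------------------------------------------- event taxonomy

def count_events(transcripts: list[Transcript],
                 models: Mapping[str, GeneModel],
                 link_dist: int = 5,
                 position_tol: int = POSITION_TOL,
                 by_cell: bool = True) -> list[EventCounts]:
    """Classify isoform-generating events per (cell, gene).

    cassette = #exon structures - 1; tss/tts = sum over anchor-exon
    contexts of (#end clusters observed - 1); position = sum over
    (structure, junction coordinate) of (#positions distinct beyond
    +-position_tol - 1). Cluster databases (end clusters per anchor exon,
    junction positions per gene) are built from all transcripts of the gene
    and each cell's transcripts are mapped back onto them, so the same
    variant is named consistently across cells. Intron-retention and ERCC
    transcripts are excluded.
    """
    per_gene: dict[str, list[Transcript]] = defaultdict(list)
    for t in transcripts:
        if t.is_ercc:
            continue
        model = models.get(t.gene_id)
        if model is not None and has_intron_retention(t, model):
            continue
        per_gene[t.gene_id].append(t)

    out = []
    for gene in sorted(per_gene):
        everyone = per_gene[gene]
        model = models.get(gene)
        # per-gene databases: end clusters per (side, anchor exon),
        # junction-position clusters pooled over all structures
        end_map: dict[tuple, int] = {}
        for side in ("5p", "3p"):
            anchors: dict[int, list[int]] = defaultdict(list)
            for t in everyone:
                anchors[_anchor_exon(t, model, side)].append(
                    t.end5 if side == "5p" else t.end3)
            for anchor, vals in anchors.items():
                for k, cl in enumerate(build_end_clusters(vals, link_dist)):
                    for v in cl:
                        end_map[(side, anchor, v)] = k
        jmap: dict[int, int] = {}
        pooled = {v for t in everyone for v in t.junction_chain()}
        for k, cl in enumerate(build_end_clusters(pooled, position_tol)):
            for v in cl:
                jmap[v] = k

        cells: dict[str, list[Transcript]] = defaultdict(list)
        for t in everyone:
            cells[t.cell_barcode if by_cell else "pooled"].append(t)
        for cell in sorted(cells):
            members = cells[cell]
            cassette = len({_structure_key(t, model)[1] for t in members}) - 1
            tss = tts = 0
            for side in ("5p", "3p"):
                seen: dict[int, set] = defaultdict(set)
                for t in members:
                    anchor = _anchor_exon(t, model, side)
                    pos = t.end5 if side == "5p" else t.end3
                    seen[anchor].add(end_map[(side, anchor, pos)])
                n_events = sum(len(s) - 1 for s in seen.values())
                if side == "5p":
                    tss = n_events
                else:
                    tts = n_events
            position = 0
            by_structure: dict[tuple, list[Transcript]] = defaultdict(list)
            for t in members:
                by_structure[_structure_key(t, model)].append(t)
            for skey, ts in sorted(by_structure.items()):
                for i in range(2 * (skey[2] - 1)):
                    clusters = {jmap[t.junction_chain()[i]] for t in ts}
                    position += len(clusters) - 1
            out.append(EventCounts(cell=cell, gene_id=gene, n_tss=tss,
                                   n_tts=tts, n_position=position,
                                   n_cassette=cassette))
    return out


def event_mix(counts: list[EventCounts]) -> dict[str, float]:
    """Percentage contribution of each event class to the total."""
    tot = sum(c.total for c in counts)
    if tot == 0:
        return {k: float("nan") for k in ("tss", "tts", "position", "cassette")}
    return {
        "tss": 100.0 * sum(c.n_tss for c in counts) / tot,
        "tts": 100.0 * sum(c.n_tts for c in counts) / tot,
        "position": 100.0 * sum(c.n_position for c in counts) / tot,
        "cassette": 100.0 * sum(c.n_cassette for c in counts) / tot,
    }


# ------------------------------------------------------- exact tests

def exon_connectivity_test(transcripts: list[Transcript], model: GeneModel,
                           exon_a: int, exon_b: int) -> tuple[float, np.ndarray]:
    """Two-sided Fisher exact test of co-inclusion of two cassette exons.

    Only transcripts whose aligned span covers both exon loci contribute
    (absence is unobservable otherwise). Returns (p, 2x2 table) with table
    rows = exon_a in/out, columns = exon_b in/out.
    """
    exons = model.exons if model.strand == "+" else model.exons[::-1]
    loci = (exons[exon_a], exons[exon_b])
    table = np.zeros((2, 2), dtype=int)
    for t in transcripts:
        if t.gene_id != model.gene_id:
            continue
        span = (t.blocks[0][0], t.blocks[-1][1])
        if not all(span[0] <= a and b <= span[1] for a, b in loci):
            continue
        present = model.overlapped_exons(t.blocks)
        table[0 if exon_a in present else 1, 0 if exon_b in present else 1] += 1
    if table.sum() == 0:
        return 1.0, table
    return float(sps.fisher_exact(table, alternative="two-sided")[1]), table


def wilcoxon_signed_rank(diffs: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p for paired differences: exact null
    for small tie-free samples, normal approximation with tie correction
    otherwise. All-zero differences give p = 1 (degenerate)."""
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) == 0 or np.all(d == 0):
        return 1.0
    nz = d[d != 0]
    exact_ok = len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)
    res = sps.wilcoxon(d, alternative="two-sided",
                       method="exact" if exact_ok else "approx",
                       zero_method="wilcox")
    return float(res.pvalue)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p for two independent
    samples."""
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def coding_vs_noncoding_test(records: list[OffsetRecord],
                             sites: tuple[str, ...] = ("junction_start",
                                                       "junction_end"),
                             method: str = "ranksum") -> dict[str, float]:
    """Compare |offset| between coding and non-coding sites, per site class.

    Default is the rank-sum form (coding and non-coding sites are
    independent sets); method='signed_rank' pairs per-gene mean |offset|
    where a gene contributes both classes.
    """
    out = {}
    for site in sites:
        coding = [abs(r.offset) for r in records
                  if r.site == site and r.coding == "coding"]
        noncod = [abs(r.offset) for r in records
                  if r.site == site and r.coding == "noncoding"]
        if method == "ranksum":
            out[site] = rank_sum_test(coding, noncod)
        elif method == "signed_rank":
            per_gene: dict[str, dict[str, list[int]]] = defaultdict(
                lambda: {"coding": [], "noncoding": []})
            for r in records:
                if r.site == site and r.coding in ("coding", "noncoding"):
                    per_gene[r.context[0]][r.coding].append(abs(r.offset))
            diffs = [float(np.mean(v["coding"]) - np.mean(v["noncoding"]))
                     for v in per_gene.values()
                     if v["coding"] and v["noncoding"]]
            out[site] = wilcoxon_signed_rank(diffs) if diffs else float("nan")
        else:
            raise DataError(f"unknown method {method!r}")
    return out


# ------------------------------------------------------- sharing & majors

@dataclass
class SharingSummary:
    venn_counts: dict[frozenset, int]
    n_isoforms: int
    frac_any_two: float
    frac_all_shared: float
    shared_expression: list[int] = field(default_factory=list)
    unique_expression: list[int] = field(default_factory=list)


def isoform_sharing(isoforms: list[Isoform],
                    celltype_of: Mapping[str, str]) -> SharingSummary:
    """Sharing of isoforms across cell types.

    Isoforms must come from one pooled isoform-calling run (keys are only
    comparable within a run). Restricted to genes represented by at least
    one transcript in every cell type.
    """
    all_types = sorted(set(celltype_of.values()))
    if len(all_types) < 2:
        raise DataError("isoform sharing needs >= 2 cell types")
    gene_presence: dict[str, set] = defaultdict(set)
    for iso in isoforms:
        for t in iso.transcripts:
            gene_presence[iso.gene_id].add(celltype_of[t.cell_barcode])
    eligible = {g for g, seen in gene_presence.items()
                if seen == set(all_types)}
    venn: dict[frozenset, int] = Counter()
    shared_expr, unique_expr = [], []
    n = 0
    n_any_two = n_all = 0
    for iso in isoforms:
        if iso.gene_id not in eligible:
            continue
        region = frozenset(celltype_of[t.cell_barcode] for t in iso.transcripts)
        venn[region] += 1
        n += 1
        if len(region) >= 2:
            n_any_two += 1
            shared_expr.append(iso.n_transcripts)
        else:
            unique_expr.append(iso.n_transcripts)
        if len(region) == len(all_types):
            n_all += 1
    return SharingSummary(
        venn_counts=dict(venn), n_isoforms=n,
        frac_any_two=(n_any_two / n if n else float("nan")),
        frac_all_shared=(n_all / n if n else float("nan")),
        shared_expression=shared_expr, unique_expression=unique_expr,
    )


def major_isoform_fraction(isoforms: list[Isoform],
                           min_transcripts: int = 10) -> dict[str, float]:
    """Per gene with more than min_transcripts transcripts: fraction of the
    gene's transcripts carried by its best-supported isoform."""
    per_gene: dict[str, list[int]] = defaultdict(list)
    for iso in isoforms:
        per_gene[iso.gene_id].append(iso.n_transcripts)
    return {
        g: max(v) / sum(v)
        for g, v in sorted(per_gene.items())
        if sum(v) > min_transcripts
    }


# ------------------------------------------------------- histograms

OFFSET_BIN_LABELS = ("<-100", "-100..-11", "-10..-6", "-5..-2", "-1", "0",
                     "+1", "+2..+5", "+6..+10", "+11..+100", ">+100")


def offset_histogram(offsets: Iterable[int]) -> "OrderedDict[str, int]":
    """Histogram with the variable bin layout used for offset profiles:
    single-bp bins near zero, widening with distance."""
    edges = [(-(10 ** 9), -101), (-100, -11), (-10, -6), (-5, -2), (-1, -1),
             (0, 0), (1, 1), (2, 5), (6, 10), (11, 100), (101, 10 ** 9)]
    hist = OrderedDict((lab, 0) for lab in OFFSET_BIN_LABELS)
    for o in offsets:
        for (lo, hi), lab in zip(edges, OFFSET_BIN_LABELS):
            if lo <= o <= hi:
                hist[lab] += 1
                break
    return hist
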