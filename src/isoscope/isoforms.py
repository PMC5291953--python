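"""Isoform definition from UMI-consensus transcripts.

Three strictness levels:

* full — identity of the exact junction chain plus shared 5' and 3'
  single-linkage end clusters (positions linked at <= 5 bp);
* conservative — full-length transcripts only (annotated first exon +
  poly(A)), with junction chains differing by <= 1 bp per coordinate
  collapsed;
* cassette — identity of annotated exon membership only.

End clusters are built per (gene, side, anchor exon): transcripts can only
share a start/end cluster if they start/end in the same annotated exon.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .errors import DataError
from .types import EndCluster, GeneModel, Isoform, Transcript

LINK_DIST = 5
JUNCTION_TOL = 1


def build_end_clusters(positions, link_dist: int = LINK_DIST) -> list[tuple[int, ...]]:
    """Single-linkage clusters of integer positions: connected components of
    the graph with an edge wherever |a - b| <= link_dist. On a line this is
    a sorted sweep; output is independent of input order."""
    pos = sorted(positions)
    if not pos:
        return []
    clusters = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] <= link_dist:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return [tuple(c) for c in clusters]


def _anchor_exon(t: Transcript, model: GeneModel | None, side: str) -> int:
    """Annotated exon index (transcript orientation) anchoring the 5' or 3'
    terminal block; -1 if the terminal block overlaps no annotated exon."""
    if model is None:
        return 0
    block = t.blocks[0] if (t.strand == "+") == (side == "5p") else t.blocks[-1]
    hit = model.overlapped_exons((block,))
    if not hit:
        return -1
    return min(hit) if side == "5p" else max(hit)


@dataclass
class ClusterSet:
    """End clusters indexed by (gene, side, anchor exon)."""

    link_dist: int = LINK_DIST
    clusters: dict[tuple, list[EndCluster]] = field(default_factory=dict)
    _lookup: dict[tuple, int] = field(default_factory=dict)

    def add_context(self, gene_id: str, side: str, anchor: int, positions):
        key = (gene_id, side, anchor)
        ecs = []
        for k, members in enumerate(build_end_clusters(positions, self.link_dist)):
            ec = EndCluster(gene_id=gene_id, side=side, anchor_exon=anchor,
                            cluster_id=k, members=members)
            ecs.append(ec)
            for p in set(members):
                self._lookup[key + (p,)] = k
        self.clusters[key] = ecs

    def cluster_of(self, gene_id: str, side: str, anchor: int, pos: int) -> int:
        try:
            return self._lookup[(gene_id, side, anchor, pos)]
        except KeyError:
            raise DataError(
                f"position {pos} not covered by any {side} cluster of "
                f"{gene_id} (anchor exon {anchor})") from None

    def widths(self) -> list[int]:
        """Cluster widths, reported for QC (single linkage can chain)."""
        return [ec.range[1] - ec.range[0]
                for ecs in self.clusters.values() for ec in ecs]


def build_transcript_end_clusters(transcripts: list[Transcript],
                                  models: dict[str, GeneModel],
                                  link_dist: int = LINK_DIST) -> ClusterSet:
    ends: dict[tuple, list[int]] = defaultdict(list)
    for t in transcripts:
        model = models.get(t.gene_id)
        ends[(t.gene_id, "5p", _anchor_exon(t, model, "5p"))].append(t.end5)
        ends[(t.gene_id, "3p", _anchor_exon(t, model, "3p"))].append(t.end3)
    cs = ClusterSet(link_dist=link_dist)
    for (gene, side, anchor), positions in sorted(ends.items()):
        cs.add_context(gene, side, anchor, positions)
    return cs


def assign_isoforms(transcripts: list[Transcript], clusters: ClusterSet,
                    models: dict[str, GeneModel]) -> list[Isoform]:
    """Full-level isoforms: key = (gene, 5' cluster, exact junction chain,
    3' cluster). Every transcript lands in exactly one isoform."""
    table: dict[tuple, Isoform] = {}
    for t in transcripts:
        model = models.get(t.gene_id)
        a5 = _anchor_exon(t, model, "5p")
        a3 = _anchor_exon(t, model, "3p")
        c5 = clusters.cluster_of(t.gene_id, "5p", a5, t.end5)
        c3 = clusters.cluster_of(t.gene_id, "3p", a3, t.end3)
        chain = t.junction_chain()
        key = (t.gene_id, (a5, c5), chain, (a3, c3))
        iso = table.get(key)
        if iso is None:
            iso = Isoform(gene_id=t.gene_id, level="full", key=key,
                          junction_chain=chain, cluster_5p=(a5, c5),
                          cluster_3p=(a3, c3))
            table[key] = iso
        iso.transcript_ids.append(t.transcript_id)
        iso.transcripts.append(t)
    return [table[k] for k in sorted(table)]


def collapse_conservative(isoforms: list[Isoform],
                          junction_tol: int = JUNCTION_TOL) -> list[Isoform]:
    """Merge full-level isoforms whose junction chains differ by no more
    than junction_tol per coordinate (same end clusters, same exon count).

    The tolerance is applied by single-linkage clustering (link at <=
    junction_tol) of all junction coordinate values observed across the
    gene — one per-gene position database, the same range-extension rule
    used for transcript ends. 1 bp steps chain, so a junction observed at
    J-1, J and J+1 is one position, while values 2 bp apart with no
    intermediate stay distinct; pooling across exon structures lets a
    junction shared by several structures stabilise all of them. Distinct
    junction sites sit far apart (intron-scale gaps), so clustering the
    pooled values cannot fuse different sites. Each merged isoform is
    represented by the junction chain of its best-supported member
    (ties: lexicographically smallest chain).
    """
    gene_values: dict[str, set[int]] = defaultdict(set)
    for iso in isoforms:
        gene_values[iso.gene_id].update(iso.junction_chain)
    gene_cluster: dict[str, dict[int, int]] = {}
    for gene, values in gene_values.items():
        mapping: dict[int, int] = {}
        for k, members in enumerate(build_end_clusters(values, junction_tol)):
            for v in members:
                mapping[v] = k
        gene_cluster[gene] = mapping
    by_group: dict[tuple, list[Isoform]] = defaultdict(list)
    for iso in isoforms:
        by_group[(iso.gene_id, iso.cluster_5p, iso.cluster_3p,
                  len(iso.junction_chain))].append(iso)
    out: list[Isoform] = []
    for group_key in sorted(by_group):
        group = by_group[group_key]
        mapping = gene_cluster[group_key[0]]
        merged: dict[tuple, list[Isoform]] = defaultdict(list)
        for iso in group:
            ckey = tuple(mapping[v] for v in iso.junction_chain)
            merged[ckey].append(iso)
        for ckey in sorted(merged):
            members = sorted(merged[ckey],
                             key=lambda i: (-i.n_transcripts, i.junction_chain))
            rep = members[0]
            out.append(Isoform(
                gene_id=rep.gene_id, level="conservative",
                key=(rep.gene_id, rep.cluster_5p, ckey, rep.cluster_3p),
                junction_chain=rep.junction_chain,
                cluster_5p=rep.cluster_5p, cluster_3p=rep.cluster_3p,
                transcript_ids=[t for m in members for t in m.transcript_ids],
                transcripts=[t for m in members for t in m.transcripts]))
    return out


def cassette_isoforms(transcripts: list[Transcript],
                      models: dict[str, GeneModel]) -> list[Isoform]:
    """Cassette-level isoforms: key = (gene, set of annotated exon indices
    present). Ends and junction micro-positions are ignored; blocks
    overlapping no annotated exon are ignored for the key."""
    table: dict[tuple, Isoform] = {}
    for t in transcripts:
        model = models.get(t.gene_id)
        if model is None:
            structure = (0,)
        else:
            structure = tuple(sorted(model.overlapped_exons(t.blocks)))
        key = (t.gene_id, structure)
        iso = table.get(key)
        if iso is None:
            iso = Isoform(gene_id=t.gene_id, level="cassette", key=key,
                          junction_chain=(), cluster_5p=None, cluster_3p=None)
            table[key] = iso
        iso.transcript_ids.append(t.transcript_id)
        iso.transcripts.append(t)
    return [table[k] for k in sorted(table)]


def has_intron_retention(t: Transcript, model: GeneModel) -> bool:
    """True if any block fully spans an annotated intron (touching both
    flanking exons). Such transcripts are rare and excluded from event
    statistics."""
    for (_, ia), (ib, _) in zip(model.exons, model.exons[1:]):
        if any(a < ia and b > ib for a, b in t.blocks):
            return True
    return False


def build_isoforms(transcripts: list[Transcript],
                   models: dict[str, GeneModel],
                   level: str = "conservative",
                   link_dist: int = LINK_DIST,
                   junction_tol: int = JUNCTION_TOL) -> list[Isoform]:
    """Convenience front-end over the three levels.

    Input transcripts for the conservative level must already be restricted
    to full-length transcripts (see assemble.filter_full_length). ERCC
    transcripts are excluded from isoform calling.
    """
    transcripts = [t for t in transcripts if not t.is_ercc]
    if level == "cassette":
        return cassette_isoforms(transcripts, models)
    clusters = build_transcript_end_clusters(transcripts, models, link_dist)
    full = assign_isoforms(transcripts, clusters, models)
    if level == "full":
        return full
    if level == "conservative":
        return collapse_conservative(full, junction_tol)
    raise DataError(f"unknown isoform level {level!r}")
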