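"""Reading and writing of the pipeline's on-disk formats.

BED12 is the native alignment interchange (0-based half-open, blockStarts
relative to chromStart); GTF is 1-based inclusive and converted on the fly.
FASTQ goes through Biopython.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import Blocks, GeneModel, check_blocks


# ---------------------------------------------------------------- FASTQ

def write_fastq(path, records: Iterable[tuple[str, str]], quality_char: str = "?"):
    """Write (read_id, sequence) pairs with a constant placeholder quality
    (default '?' = Q30 Sanger)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in records:
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [ord(quality_char) - 33] * len(seq)
            SeqIO.write(rec, fh, "fastq")


def read_fastq(path) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)


# ---------------------------------------------------------------- BED12

@dataclass(frozen=True)
class Bed12Record:
    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    blocks: Blocks  # absolute genomic half-open intervals

    def to_line(self) -> str:
        sizes = ",".join(str(b - a) for a, b in self.blocks)
        starts = ",".join(str(a - self.start) for a, b in self.blocks)
        return "\t".join(
            str(x)
            for x in (
                self.chrom, self.start, self.end, self.name, self.score,
                self.strand, self.start, self.end, "0,0,0",
                len(self.blocks), sizes + ",", starts + ",",
            )
        )


def blocks_to_bed12(chrom, name, strand, blocks, score=0) -> Bed12Record:
    blocks = check_blocks(blocks)
    return Bed12Record(chrom, blocks[0][0], blocks[-1][1], name, score, strand, blocks)


def write_bed12(path, records: Iterable[Bed12Record]):
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_bed12(path) -> list[Bed12Record]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, score, strand = f[3], int(float(f[4])), f[5]
                nblocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED12: {exc}") from None
            if not (len(sizes) == len(starts) == nblocks):
                raise ValueError(f"{path}:{lineno}: blockCount disagrees with lists")
            blocks = tuple((start + s, start + s + z) for s, z in zip(starts, sizes))
            out.append(Bed12Record(chrom, start, end, name, score, strand, blocks))
    return out


# ---------------------------------------------------------------- GTF / BED6

def write_gtf(path, models: Iterable[GeneModel], source: str = "isoscope"):
    """One gene/transcript per model plus exon and CDS features (1-based
    inclusive coordinates, per the GTF standard)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.1";'
            rows = [("transcript", m.span[0], m.span[1])]
            rows += [("exon", a, b) for a, b in m.exons]
            rows += [("CDS", a, b) for a, b in m.cds_intervals]
            for feat, a, b in rows:
                fh.write(
                    "\t".join(
                        (m.chrom, source, feat, str(a + 1), str(b), ".", m.strand,
                         ".", attrs)
                    )
                    + "\n"
                )


def read_gtf(path) -> dict[str, GeneModel]:
    """Rebuild GeneModels from a GTF written by write_gtf (exon + CDS rows)."""
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, feat, a, b, _, strand, _, attrs = f[:9]
            gid = attrs.split('gene_id "', 1)[1].split('"', 1)[0]
            meta[gid] = (chrom, strand)
            iv = (int(a) - 1, int(b))
            if feat == "exon":
                exons.setdefault(gid, []).append(iv)
            elif feat == "CDS":
                cds.setdefault(gid, []).append(iv)
    return {
        gid: GeneModel(
            gene_id=gid,
            chrom=meta[gid][0],
            strand=meta[gid][1],
            exons=tuple(sorted(exons[gid])),
            cds_intervals=tuple(sorted(cds.get(gid, []))),
        )
        for gid in exons
    }


def write_coding_bed(path, models: Iterable[GeneModel]):
    """CCDS-style BED6 of coding intervals (name = gene id)."""
    with open(path, "w") as fh:
        for m in models:
            for a, b in m.cds_intervals:
                fh.write(f"{m.chrom}\t{a}\t{b}\t{m.gene_id}\t0\t{m.strand}\n")


def read_coding_bed(path) -> dict[str, Blocks]:
    """gene id -> sorted coding intervals."""
    out: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.split("\t")
            out.setdefault(f[3], []).append((int(f[1]), int(f[2])))
    return {g: tuple(sorted(v)) for g, v in out.items()}


# ---------------------------------------------------------------- TSV

def write_tsv(path, header: list[str], rows: Iterable[Iterable]):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def read_tsv(path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
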