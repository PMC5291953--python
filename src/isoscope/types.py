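"""Core domain types shared across the pipeline stages.

Coordinates are 0-based half-open genomic intervals throughout; 5'/3' are
transcript-orientation (strand-aware) notions. BED12 is native; GTF is
converted on read/write.
"""
from __future__ import annotations

from dataclasses import dataclass, field

Interval = tuple[int, int]
Blocks = tuple[Interval, ...]


def check_blocks(blocks) -> Blocks:
    """Validate that blocks are sorted, disjoint, each of length >= 1."""
    blocks = tuple((int(a), int(b)) for a, b in blocks)
    prev_end = None
    for a, b in blocks:
        if b - a < 1:
            raise ValueError(f"block {(a, b)} has length < 1")
        if prev_end is not None and a < prev_end:
            raise ValueError(f"blocks overlap or are unsorted at {(a, b)}")
        prev_end = b
    return blocks


@dataclass(frozen=True)
class GeneModel:
    """Annotated exon/CDS structure of one gene (its reference frame).

    One structure per gene: the annotated isoform with the most exons is the
    single reference against which reads are annotated and events are named.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Blocks
    cds_intervals: Blocks = ()
    # transcript-orientation extreme coordinates of the first/last exon
    annotated_tss: int = -1
    annotated_tts: int = -1

    def __post_init__(self):
        object.__setattr__(self, "exons", check_blocks(self.exons))
        object.__setattr__(self, "cds_intervals", check_blocks(self.cds_intervals))
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for a, b in self.cds_intervals:
            if not any(ea <= a and b <= eb for ea, eb in self.exons):
                raise ValueError("CDS interval outside exons")
        tss = self.exons[0][0] if self.strand == "+" else self.exons[-1][1]
        tts = self.exons[-1][1] if self.strand == "+" else self.exons[0][0]
        if self.annotated_tss == -1:
            object.__setattr__(self, "annotated_tss", tss)
        if self.annotated_tts == -1:
            object.__setattr__(self, "annotated_tts", tts)
        if (self.annotated_tss, self.annotated_tts) != (tss, tts):
            raise ValueError("annotated ends disagree with exon extremes")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        """Gene length: annotated TSS to TTS span."""
        return self.exons[-1][1] - self.exons[0][0]

    @property
    def first_exon(self) -> Interval:
        """First exon in transcript orientation."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def last_exon(self) -> Interval:
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    def exon_index_of(self, pos: int) -> int | None:
        """Annotated exon index (transcript orientation) containing pos."""
        for i, (a, b) in enumerate(self.exons):
            if a <= pos < b:
                return i if self.strand == "+" else len(self.exons) - 1 - i
        return None

    def overlapped_exons(self, blocks: Blocks) -> frozenset[int]:
        """Transcript-orientation indices of annotated exons overlapping blocks."""
        hit = set()
        n = len(self.exons)
        for i, (ea, eb) in enumerate(self.exons):
            if any(a < eb and ea < b for a, b in blocks):
                hit.add(i if self.strand == "+" else n - 1 - i)
        return frozenset(hit)


@dataclass(frozen=True)
class TrueMolecule:
    """A simulated pre-amplification cDNA molecule with full ground truth."""

    molecule_id: str
    gene_id: str  # gene or ERCC id
    barcode: str
    umi: str
    chrom: str
    strand: str
    exon_blocks: Blocks
    has_full_first_exon: bool
    isoform_key: str

    def __post_init__(self):
        if len(self.barcode) != 16:
            raise ValueError("barcode must be 16 bases")
        if len(self.umi) != 6:
            raise ValueError("UMI must be 6 bases")
        object.__setattr__(self, "exon_blocks", check_blocks(self.exon_blocks))


@dataclass(frozen=True)
class AdapterMatch:
    position: int
    which: str  # e.g. 'illumina', 'bc1', 'bc1_rc'
    length: int
    mismatches: int

    @property
    def end(self) -> int:
        return self.position + self.length

    @property
    def is_rc(self) -> bool:
        return self.which.endswith("_rc")

    @property
    def base(self) -> str:
        return self.which[:-3] if self.is_rc else self.which


@dataclass
class ValidRead:
    """One demultiplexed, trimmed cDNA read in transcript orientation."""

    read_id: str
    subread_index: int
    barcode: str  # the matched known barcode sequence
    umi: str
    case: int  # 1 = sense strand read, 2 = reverse-complement layout
    template_seq: str
    has_polya: bool = True
    g_run: int = 0  # length of the template-switch G-run trimmed

    @property
    def name(self) -> str:
        return f"{self.read_id}/{self.subread_index}"

    @property
    def first8(self) -> str:
        """First 8 template bases after the UMI (and G-run)."""
        return self.template_seq[:8]


@dataclass
class AlignedRead:
    read: ValidRead
    chrom: str
    strand: str
    blocks: Blocks
    gene_id: str | None = None
    is_ercc: bool = False

    def __post_init__(self):
        self.blocks = check_blocks(self.blocks)

    @property
    def aligned_bases(self) -> int:
        return sum(b - a for a, b in self.blocks)


@dataclass
class Transcript:
    """UMI-consensus molecule: reads sharing (cell, gene, UMI) collapsed."""

    cell_barcode: str
    gene_id: str
    umi: str
    chrom: str
    strand: str
    blocks: Blocks
    read_support: int
    has_polya: bool = True
    covers_first_exon: bool | None = None
    is_ercc: bool = False

    def __post_init__(self):
        self.blocks = check_blocks(self.blocks)
        if self.read_support < 1:
            raise ValueError("read_support must be >= 1")

    @property
    def transcript_id(self) -> str:
        return f"{self.cell_barcode}:{self.gene_id}:{self.umi}"

    @property
    def end5(self) -> int:
        return self.blocks[0][0] if self.strand == "+" else self.blocks[-1][1]

    @property
    def end3(self) -> int:
        return self.blocks[-1][1] if self.strand == "+" else self.blocks[0][0]

    def junction_chain(self) -> tuple[int, ...]:
        """Internal junction coordinates, 5'->3' in transcript orientation.

        For each intron: (donor, acceptor) genomic positions.
        """
        if len(self.blocks) == 1:
            return ()
        coords = []
        if self.strand == "+":
            for i in range(len(self.blocks) - 1):
                coords.extend((self.blocks[i][1], self.blocks[i + 1][0]))
        else:
            for i in range(len(self.blocks) - 1, 0, -1):
                coords.extend((self.blocks[i][0], self.blocks[i - 1][1]))
        return tuple(coords)


@dataclass(frozen=True)
class EndCluster:
    """Single-linkage cluster of transcript 5' or 3' end positions."""

    gene_id: str
    side: str  # '5p' or '3p'
    anchor_exon: int
    cluster_id: int
    members: tuple[int, ...]

    @property
    def range(self) -> Interval:
        return (min(self.members), max(self.members))

    def __contains__(self, pos: int) -> bool:
        return pos in set(self.members)


@dataclass
class Isoform:
    gene_id: str
    level: str  # 'full', 'conservative', 'cassette'
    key: tuple
    junction_chain: tuple[int, ...]
    cluster_5p: int | None
    cluster_3p: int | None
    transcript_ids: list[str] = field(default_factory=list)
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)


@dataclass(frozen=True)
class OffsetRecord:
    site: str  # 'end5', 'end3', 'junction_start', 'junction_end'
    coding: str  # 'coding', 'noncoding', 'na'
    offset: int
    context: tuple


@dataclass
class EventCounts:
    """Isoform-generating event tallies for one (cell, gene) context.

    Each count is (#distinct variants - 1) within its context: only
    structures/clusters beyond the first are events.
    """

    cell: str
    gene_id: str
    n_tss: int = 0
    n_tts: int = 0
    n_position: int = 0
    n_cassette: int = 0

    def __post_init__(self):
        for v in (self.n_tss, self.n_tts, self.n_position, self.n_cassette):
            if v < 0:
                raise ValueError("event counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_tss + self.n_tts + self.n_position + self.n_cassette
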