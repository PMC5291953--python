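"""Synthetic STRT/long-read data generator with full ground truth.

Emulates the read grammar of barcoded, UMI-tagged full-length cDNA sequenced
as circular-consensus long reads:

    case 1:  barcode + Illumina adapter + UMI(6) + GGG + template + polyA
             + rc(Illumina adapter) + rc(barcode)
    case 2:  the reverse complement of the same layout (the other strand of
             the insert was read).

On top of the grammar it reproduces the noise sources the pipeline must
tolerate: concatemerization of 2-4 molecules during circularization, PCR
read redundancy per UMI, 5' degradation/truncation, alternative TSS/TTS and
cassette usage, +-1 bp splice-junction jitter and a few bp of end jitter,
and ERCC spike-ins with exactly known ends. Every emitted object is recorded
in truth tables, and a fixed seed gives byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as iio
from .errors import ConfigError
from .sequences import BARCODES, ILLUMINA_ADAPTER, revcomp
from .types import Blocks, GeneModel, TrueMolecule

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def serialize_blocks(chrom: str, strand: str, blocks: Blocks) -> str:
    return f"{chrom}:{strand}:" + ",".join(f"{a}-{b}" for a, b in blocks)


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults mirror the characterised error regime of UMI-tagged PacBio
    circular-consensus data: junction jitter of +-1 bp, transcript-end
    jitter of a few bp (ends are reliable to about +-5 bp), about a third
    of records being circularization concatemers, a geometric read-per-UMI
    distribution with 61% singletons, and a majority of endogenous
    molecules 5'-truncated by degradation.
    """

    seed: int = 1
    # gene models
    n_genes: int = 50
    exon_count: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (100, 500)
    cds_margin: int = 150  # UTR-like margin excluded from CDS at each end
    isoforms_per_gene: int = 3
    isoform_weights: tuple[float, ...] | None = (0.5, 0.3, 0.2)
    # ERCC spike-ins
    n_ercc: int = 92
    ercc_length: tuple[int, int] = (255, 2007)
    ercc_fraction: float = 0.05
    # cells and molecules
    n_cells: int = 3
    molecules_per_cell: int = 700
    degradation_rate: float = 0.7
    # read emission
    reads_per_umi_mean: float = 1.6
    concatemer_rate: float = 0.33
    concatemer_arity: tuple[int, int] = (2, 4)
    p_case2: float = 0.5
    polya_length: int = 30
    # noise (max |offset| in bp; offsets uniform on the signed range)
    junction_noise: int = 1
    end_noise_5p: int = 4
    end_noise_3p: int = 4

    def validate(self) -> "SimConfig":
        errs = []
        for name in ("ercc_fraction", "degradation_rate", "concatemer_rate", "p_case2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name}={v} outside [0, 1]")
        for name in ("n_genes", "n_cells", "molecules_per_cell", "n_ercc",
                     "polya_length", "isoforms_per_gene"):
            if getattr(self, name) < 1:
                errs.append(f"{name} must be >= 1")
        for name in ("junction_noise", "end_noise_5p", "end_noise_3p", "cds_margin"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0")
        for name in ("exon_count", "exon_length", "intron_length", "ercc_length",
                     "concatemer_arity"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                errs.append(f"{name}=({lo},{hi}) is not a valid range")
        if self.reads_per_umi_mean < 1.0:
            errs.append("reads_per_umi_mean must be >= 1")
        if self.polya_length < 10:
            errs.append("polya_length below the 10-base detection threshold")
        if self.concatemer_arity[0] < 2:
            errs.append("concatemer arity must be >= 2")
        if self.isoforms_per_gene > 5:
            errs.append("at most 5 distinct isoform variants per gene are supported")
        if self.isoforms_per_gene >= 2:
            if self.exon_count[0] < 3:
                errs.append("isoform variants require at least 3 exons per gene")
            if self.exon_length[0] < 60:
                errs.append("isoform variants require exon_length >= 60 "
                            "(alternative ends shift 20 bp inside terminal exons)")
        if self.isoforms_per_gene >= 5 and self.exon_count[0] < 4:
            errs.append("5 isoform variants require at least 4 exons per gene")
        if self.isoform_weights is not None:
            w = self.isoform_weights
            if len(w) != self.isoforms_per_gene:
                errs.append("isoform_weights length must equal isoforms_per_gene")
            elif min(w) <= 0:
                errs.append("isoform_weights must be positive")
        if self.intron_length[0] <= 40 + 2 * self.junction_noise:
            errs.append("intron_length must exceed the 40 bp block-merge gap "
                        "plus junction noise")
        if errs:
            raise ConfigError("; ".join(errs))
        return self


class Reference:
    """In-memory random reference: chromosome name -> sequence."""

    def __init__(self):
        self.chroms: dict[str, str] = {}

    def add(self, name: str, seq: str):
        self.chroms[name] = seq

    def fetch(self, chrom: str, blocks: Blocks, strand: str) -> str:
        """Spliced sequence of blocks in transcript orientation."""
        seq = self.chroms[chrom]
        s = "".join(seq[a:b] for a, b in blocks)
        return s if strand == "+" else revcomp(s)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode("ascii")


# ------------------------------------------------------------ gene models

def _transcript_to_genomic(exons: Blocks, strand: str, t_a: int, t_b: int) -> Blocks:
    """Map transcript-coordinate range [t_a, t_b) onto genomic intervals."""
    order = exons if strand == "+" else exons[::-1]
    out = []
    off = 0
    for a, b in order:
        ln = b - a
        lo, hi = max(t_a - off, 0), min(t_b - off, ln)
        if lo < hi:
            if strand == "+":
                out.append((a + lo, a + hi))
            else:
                out.append((b - hi, b - lo))
        off += ln
    return tuple(sorted(out))


def generate_gene_models(cfg: SimConfig, rng: np.random.Generator | None = None,
                         reference: Reference | None = None) -> dict[str, GeneModel]:
    """Generate n_genes reference gene structures on one chromosome.

    Each gene's CDS excludes a UTR-like margin (cfg.cds_margin, shrunk for
    short genes) at both transcript ends, so coding and non-coding junction
    classes both occur.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.exon_length[1] * cfg.exon_count[1] < cfg.exon_length[0] * cfg.exon_count[0]:
        raise ConfigError("exon length distribution cannot fit requested exon count")
    models: dict[str, GeneModel] = {}
    cursor = 500
    chrom = "chrS"
    for g in range(cfg.n_genes):
        n_exons = int(rng.integers(cfg.exon_count[0], cfg.exon_count[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for i in range(n_exons):
            ln = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append((pos, pos + ln))
            pos += ln
            if i < n_exons - 1:
                pos += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        exons = tuple(exons)
        mrna_len = sum(b - a for a, b in exons)
        margin = min(cfg.cds_margin, max((mrna_len - 60) // 2, 0))
        cds = _transcript_to_genomic(exons, strand, margin, mrna_len - margin)
        # clip CDS to exon boundaries (it is by construction, but keep sorted)
        models[f"gene{g + 1:04d}"] = GeneModel(
            gene_id=f"gene{g + 1:04d}", chrom=chrom, strand=strand,
            exons=exons, cds_intervals=cds,
        )
        cursor = pos + 1000  # intergenic gap
    if reference is not None:
        reference.add(chrom, _random_seq(rng, cursor + 500))
    return models


def generate_ercc_set(n: int = 92, len_min: int = 255, len_max: int = 2007,
                      rng: np.random.Generator | None = None,
                      reference: Reference | None = None) -> dict[str, GeneModel]:
    """n single-exon spike-in models with exactly known 5'/3' ends."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    if len_min > len_max or len_min < 1:
        raise ConfigError("invalid ERCC length range")
    rng = np.random.default_rng(0) if rng is None else rng
    models = {}
    for i in range(n):
        eid = f"ERCC-{i + 1:05d}"
        ln = int(rng.integers(len_min, len_max + 1))
        models[eid] = GeneModel(gene_id=eid, chrom=eid, strand="+", exons=((0, ln),))
        if reference is not None:
            reference.add(eid, _random_seq(rng, ln))
    return models


# ------------------------------------------------------------ true isoforms

def _isoform_variants(model: GeneModel, k: int, rng: np.random.Generator) -> list[Blocks]:
    """k distinct true isoform block structures for one gene.

    Variant kinds: canonical; internal-cassette exclusion; alternative TSS
    (+20 bp inside the first exon); alternative TTS (-20 bp inside the last
    exon); a 6 bp donor shift at one internal junction. All variants remain
    distinguishable under the pipeline's 5 bp end clustering and +-1 bp
    junction tolerance.
    """
    exons = list(model.exons)
    n = len(exons)
    internal = list(range(1, n - 1))
    variants: list[Blocks] = [tuple(exons)]
    if k >= 2:
        drop = internal[int(rng.integers(len(internal)))]
        variants.append(tuple(e for i, e in enumerate(exons) if i != drop))
    if k >= 3:
        blocks = list(exons)
        if model.strand == "+":
            a, b = blocks[0]
            blocks[0] = (a + 20, b)
        else:
            a, b = blocks[-1]
            blocks[-1] = (a, b - 20)
        variants.append(tuple(blocks))
    if k >= 4:
        blocks = list(exons)
        if model.strand == "+":
            a, b = blocks[-1]
            blocks[-1] = (a, b - 20)
        else:
            a, b = blocks[0]
            blocks[0] = (a + 20, b)
        variants.append(tuple(blocks))
    if k >= 5:
        j = internal[int(rng.integers(len(internal)))]
        blocks = list(exons)
        a, b = blocks[j]
        blocks[j] = (a, b - 6) if model.strand == "+" else (a + 6, b)
        variants.append(tuple(blocks))
    return variants[:k]


@dataclass
class SimResult:
    config: SimConfig
    models: dict[str, GeneModel]
    ercc_models: dict[str, GeneModel]
    reference: Reference
    molecules: list[TrueMolecule]
    isoform_truth: dict[str, list[str]]  # gene -> configured isoform keys
    fastq: list[tuple[str, str]] = field(default_factory=list)
    alignments: list[iio.Bed12Record] = field(default_factory=list)
    read_truth: list[dict] = field(default_factory=list)

    @property
    def cell_barcodes(self) -> list[str]:
        return sorted({m.barcode for m in self.molecules})

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        iio.write_fastq(outdir / "reads.fastq", self.fastq)
        iio.write_bed12(outdir / "alignments.bed", self.alignments)
        iio.write_gtf(outdir / "genes.gtf", self.models.values())
        iio.write_coding_bed(outdir / "ccds.bed", self.models.values())
        iio.write_tsv(
            outdir / "ercc.tsv", ["ercc_id", "length"],
            [(m.gene_id, m.exons[0][1]) for m in self.ercc_models.values()],
        )
        iio.write_tsv(
            outdir / "molecules.tsv",
            ["molecule_id", "source_id", "barcode", "umi", "chrom", "strand",
             "blocks", "has_full_first_exon", "isoform_key"],
            [
                (m.molecule_id, m.gene_id, m.barcode, m.umi, m.chrom, m.strand,
                 ",".join(f"{a}-{b}" for a, b in m.exon_blocks),
                 int(m.has_full_first_exon), m.isoform_key)
                for m in self.molecules
            ],
        )
        iio.write_tsv(
            outdir / "read_truth.tsv",
            ["read_id", "subread_index", "arity", "molecule_id", "case"],
            [
                (r["read_id"], r["subread_index"], r["arity"], r["molecule_id"],
                 r["case"])
                for r in self.read_truth
            ],
        )


def sample_true_molecules(models: dict[str, GeneModel],
                          ercc_models: dict[str, GeneModel],
                          cfg: SimConfig,
                          rng: np.random.Generator) -> tuple[list[TrueMolecule], dict]:
    """Draw per-cell molecules with gene/isoform weights and 5' degradation.

    A degraded molecule loses at least its entire first exon (its 3' end
    stays intact) and is flagged has_full_first_exon=False.
    """
    if not models:
        raise ConfigError("gene model set must be non-empty")
    gene_ids = sorted(models)
    ercc_ids = sorted(ercc_models) if ercc_models else []
    variants: dict[str, list[Blocks]] = {}
    truth_keys: dict[str, list[str]] = {}
    weights = cfg.isoform_weights
    if weights is None:
        weights = tuple([1.0 / cfg.isoforms_per_gene] * cfg.isoforms_per_gene)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    for g in gene_ids:
        variants[g] = _isoform_variants(models[g], cfg.isoforms_per_gene, rng)
        truth_keys[g] = [
            serialize_blocks(models[g].chrom, models[g].strand, v)
            for v in variants[g]
        ]
    cells = sorted(BARCODES.values())[: cfg.n_cells]
    molecules: list[TrueMolecule] = []
    idx = 0
    for cell in cells:
        for _ in range(cfg.molecules_per_cell):
            idx += 1
            umi = _random_seq(rng, 6)
            if ercc_ids and rng.random() < cfg.ercc_fraction:
                eid = ercc_ids[int(rng.integers(len(ercc_ids)))]
                em = ercc_models[eid]
                molecules.append(TrueMolecule(
                    molecule_id=f"mol{idx:06d}", gene_id=eid, barcode=cell,
                    umi=umi, chrom=em.chrom, strand="+",
                    exon_blocks=em.exons, has_full_first_exon=True,
                    isoform_key=serialize_blocks(em.chrom, "+", em.exons),
                ))
                continue
            gid = gene_ids[int(rng.integers(len(gene_ids)))]
            model = models[gid]
            blocks = variants[gid][int(rng.choice(len(w), p=w))]
            full = True
            if rng.random() < cfg.degradation_rate and len(blocks) > 1:
                # drop >= 1 5'-most exon, then start inside the next one
                tblocks = blocks if model.strand == "+" else blocks[::-1]
                n_drop = int(rng.integers(1, len(tblocks)))
                kept = list(tblocks[n_drop:])
                a, b = kept[0]
                room = max(b - a - 30, 0)
                off = int(rng.integers(0, room + 1)) if room else 0
                kept[0] = (a + off, b) if model.strand == "+" else (a, b - off)
                blocks = tuple(sorted(kept))
                full = False
            molecules.append(TrueMolecule(
                molecule_id=f"mol{idx:06d}", gene_id=gid, barcode=cell,
                umi=umi, chrom=model.chrom, strand=model.strand,
                exon_blocks=blocks, has_full_first_exon=full,
                isoform_key=serialize_blocks(model.chrom, model.strand, blocks),
            ))
    return molecules, truth_keys


# ------------------------------------------------------------ read emission

def _apply_noise(mol: TrueMolecule, cfg: SimConfig,
                 rng: np.random.Generator, chrom_len: int) -> Blocks:
    blocks = [list(b) for b in mol.exon_blocks]
    j = cfg.junction_noise
    if j > 0 and len(blocks) > 1:
        for i in range(len(blocks) - 1):
            blocks[i][1] += int(rng.integers(-j, j + 1))
            blocks[i + 1][0] += int(rng.integers(-j, j + 1))
    e5, e3 = cfg.end_noise_5p, cfg.end_noise_3p
    if mol.strand == "-":  # genomic low coordinate is the 3' end
        e5, e3 = e3, e5
    lo_shift = int(rng.integers(-e5, e5 + 1)) if e5 else 0
    hi_shift = int(rng.integers(-e3, e3 + 1)) if e3 else 0
    blocks[0][0] += lo_shift
    blocks[-1][1] += hi_shift
    # clamp to the chromosome and keep blocks valid
    blocks[0][0] = max(blocks[0][0], 0)
    blocks[-1][1] = min(blocks[-1][1], chrom_len)
    out = []
    prev_end = None
    for a, b in blocks:
        if prev_end is not None:
            a = max(a, prev_end + 1)
        b = max(b, a + 1)
        out.append((a, b))
        prev_end = b
    return tuple(out)


def emit_reads(molecules: list[TrueMolecule], reference: Reference,
               cfg: SimConfig, rng: np.random.Generator,
               ) -> tuple[list[tuple[str, str]], list[iio.Bed12Record], list[dict]]:
    """Emit FASTQ records (with PCR redundancy, concatemers, strand cases and
    coordinate noise) plus the per-subread BED12 standing in for the spliced
    aligner output, and a per-subread truth table."""
    if not molecules:
        raise ConfigError("molecule list must be non-empty")
    p = 1.0 / cfg.reads_per_umi_mean
    units: list[TrueMolecule] = []
    for mol in molecules:
        for _ in range(int(rng.geometric(p))):
            units.append(mol)
    order = rng.permutation(len(units))
    units = [units[i] for i in order]
    fastq: list[tuple[str, str]] = []
    bed: list[iio.Bed12Record] = []
    truth: list[dict] = []
    pos = 0
    ridx = 0
    lo_k, hi_k = cfg.concatemer_arity
    while pos < len(units):
        if rng.random() < cfg.concatemer_rate:
            k = int(rng.integers(lo_k, hi_k + 1))
        else:
            k = 1
        group = units[pos: pos + k]
        pos += k
        ridx += 1
        rid = f"read{ridx:06d}"
        parts = []
        for sub, mol in enumerate(group):
            chrom_len = len(reference.chroms[mol.chrom])
            blocks = _apply_noise(mol, cfg, rng, chrom_len)
            template = reference.fetch(mol.chrom, blocks, mol.strand)
            layout = (mol.barcode + ILLUMINA_ADAPTER + mol.umi + "GGG"
                      + template + "A" * cfg.polya_length
                      + revcomp(ILLUMINA_ADAPTER) + revcomp(mol.barcode))
            case = 2 if rng.random() < cfg.p_case2 else 1
            parts.append(layout if case == 1 else revcomp(layout))
            bed.append(iio.blocks_to_bed12(
                mol.chrom, f"{rid}/{sub}", mol.strand, blocks))
            truth.append({
                "read_id": rid, "subread_index": sub, "arity": len(group),
                "molecule_id": mol.molecule_id, "case": case,
                "barcode": mol.barcode, "umi": mol.umi,
            })
        fastq.append((rid, "".join(parts)))
    return fastq, bed, truth


def simulate(cfg: SimConfig, outdir=None) -> SimResult:
    """Run the full generator: models, spike-ins, molecules, reads."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    reference = Reference()
    models = generate_gene_models(cfg, rng, reference)
    ercc = generate_ercc_set(cfg.n_ercc, *cfg.ercc_length, rng=rng,
                             reference=reference)
    molecules, truth_keys = sample_true_molecules(models, ercc, cfg, rng)
    fastq, bed, read_truth = emit_reads(molecules, reference, cfg, rng)
    result = SimResult(
        config=cfg, models=models, ercc_models=ercc, reference=reference,
        molecules=molecules, isoform_truth=truth_keys, fastq=fastq,
        alignments=bed, read_truth=read_truth,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
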