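import pytest

from isoscope.simulate import SimConfig, simulate
from isoscope.types import GeneModel


def small_config(**overrides) -> SimConfig:
    """A fast simulation: few genes, few molecules, defaults otherwise."""
    kwargs = dict(seed=11, n_genes=8, n_cells=2, molecules_per_cell=120)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def noise_free_config(**overrides) -> SimConfig:
    kwargs = dict(junction_noise=0, end_noise_5p=0, end_noise_3p=0,
                  degradation_rate=0.0)
    kwargs.update(overrides)
    return small_config(**kwargs)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free simulation: truth should round-trip exactly."""
    return simulate(noise_free_config())


_UMI_COUNTER = [0]


def make_transcript(blocks, strand="+", gene_id="g1", chrom="chr1",
                    cell="c1", umi=None, support=1, **kwargs):
    from isoscope.types import Transcript
    if umi is None:
        _UMI_COUNTER[0] += 1
        umi = f"{_UMI_COUNTER[0]:06d}"
    return Transcript(cell_barcode=cell, gene_id=gene_id, umi=umi,
                      chrom=chrom, strand=strand, blocks=tuple(blocks),
                      read_support=support, **kwargs)


def toy_gene(strand="+", gene_id="g1", chrom="chr1") -> GeneModel:
    """Four exons of 100 bp separated by 100 bp introns, CDS excluding
    60 bp UTR-like margins at both transcript ends."""
    exons = ((100, 200), (300, 400), (500, 600), (700, 800))
    if strand == "+":
        cds = ((160, 200), (300, 400), (500, 600), (700, 740))
    else:
        cds = ((160, 200), (300, 400), (500, 600), (700, 740))
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     exons=exons, cds_intervals=cds)
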