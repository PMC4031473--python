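import pytest

from chipexpr import GeneModel, GenomicInterval, Peak, SyntheticConfig, generate


def make_peak(chrom="chr1", start=100, end=200, name="p", summit=None,
              fold=20.0, score=5.0):
    if summit is None:
        summit = (start + end) // 2
    return Peak(GenomicInterval(chrom, start, end, "."), name, summit, fold, score)


def make_gene(gene_id="G1", chrom="chr1", strand="+", tx_start=1000,
              tx_end=5000, cds_start=None, cds_end=None,
              exon_starts=(), exon_ends=()):
    return GeneModel(gene_id, chrom, strand, tx_start, tx_end,
                     cds_start, cds_end, exon_starts, exon_ends)


SMALL_CONFIG = dict(n_chroms=1, chrom_length=1_200_000, n_genes=60,
                    n_peaks=40, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact fully-featured synthetic dataset (genome + coverage)."""
    return generate(SyntheticConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synthdata")
    ds = generate(SyntheticConfig(**SMALL_CONFIG), outdir=str(outdir))
    return ds, outdir
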