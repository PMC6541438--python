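"""Shared fixtures: a small toy reference bundle and simulated embryos."""

import pytest

from hybridxci import (
    EmbryoSimSpec,
    TranscriptomeIndex,
    make_toy_reference,
    simulate_embryo,
)
from hybridxci.pseudogenome import strain_transcriptome, substitute_snps
from hybridxci.simulate import DEFAULT_SILENCING


@pytest.fixture(scope="session")
def small_reference():
    """20-gene bundle (12 autosomal + 8 X) used across assignment tests."""
    genomes, variants, genes = make_toy_reference(
        n_autosomal_genes=12, n_x_genes=8, gene_len=500, seed=11
    )
    return genomes, variants, genes


@pytest.fixture(scope="session")
def strain_bundle(small_reference):
    genomes, variants, genes = small_reference
    mat = substitute_snps(genomes, variants, "maternal")
    pat = substitute_snps(genomes, variants, "paternal")
    mat_tx = strain_transcriptome(mat, genes)
    pat_tx = strain_transcriptome(pat, genes)
    return mat, pat, mat_tx, pat_tx


@pytest.fixture(scope="session")
def indices(strain_bundle):
    _, _, mat_tx, pat_tx = strain_bundle
    return TranscriptomeIndex(mat_tx, k=25), TranscriptomeIndex(pat_tx, k=25)


def make_spec(embryo_id="e1", genotype="fl/fl", sex="XX", xci_mix=None,
              silencing=None, mean_depth=500.0, error_rate=0.0, seed=5,
              n_cells=64, **kw):
    if xci_mix is None:
        xci_mix = {"paternal_X_inactive": 1.0}
    if silencing is None:
        silencing = dict(DEFAULT_SILENCING)
    return EmbryoSimSpec(
        embryo_id=embryo_id, genotype=genotype, sex=sex, n_cells=n_cells,
        xci_mix=xci_mix, silencing_efficiency=silencing,
        mean_depth=mean_depth, error_rate=error_rate, seed=seed, **kw
    )


@pytest.fixture(scope="session")
def flfl_embryo(small_reference, strain_bundle):
    """Error-free imprinted-XCI embryo with complete subject-gene silencing."""
    genomes, variants, genes = small_reference
    _, _, mat_tx, pat_tx = strain_bundle
    spec = make_spec(silencing={"subject": 1.0, "escaper": 0.3, "autosomal": 0.0})
    return simulate_embryo(spec, genes, variants, genomes,
                           transcriptomes=(mat_tx, pat_tx))
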