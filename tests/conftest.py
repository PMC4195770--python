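import pytest

from trnafive.constructs import asp_gtc_construct
from trnafive.simulate import SimConfig, build_gene_set


@pytest.fixture(scope="session")
def asp_gene():
    """The reference synthetic Asp-GTC construct (75-mer with CCA)."""
    return asp_gtc_construct()


@pytest.fixture(scope="session")
def small_gene_set():
    """A deterministic 12-gene repertoire with duplicates."""
    config = SimConfig(seed=42, n_genes=12, duplicate_fraction=0.25, expression_mean=60)
    genes, truth = build_gene_set(config)
    return config, genes, truth
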