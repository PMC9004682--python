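import numpy as np
import pytest

from mcfuse import coupling, synthetic


@pytest.fixture(scope="session")
def small_multimodal():
    """A 3-cluster, half-coupled multi-modal dataset shared across tests."""
    cfg = synthetic.SyntheticConfig(
        n_cells=300, n_genes=200, n_clusters=3, coupled_fraction=0.5, seed=11
    )
    mc, rna, truth = synthetic.generate_multimodal(cfg)
    return cfg, mc, rna, truth


@pytest.fixture(scope="session")
def normalized_modalities(small_multimodal):
    """Per-cell normalized mCH and log expression matrices for the shared dataset."""
    _, mc, rna, truth = small_multimodal
    rates = mc.mc / np.maximum(mc.cov, 1)
    mch = coupling.normalize_gene_mch(rates, truth.global_mch)
    expr = coupling.normalize_expression(rna)
    return mch, expr, truth
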