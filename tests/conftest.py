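import numpy as np
import pandas as pd
import pytest

from cafstate import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ranked_list(rng):
    """A 100-gene ranked list with distinct scores."""
    genes = [f"G{i:03d}" for i in range(100)]
    return pd.Series(np.sort(rng.normal(size=100))[::-1], index=genes)


@pytest.fixture(scope="session")
def lri_tables():
    trues = [
        ("TGFB1", "TGFBR2", "cancer", "myCAF"),
        ("IL1B", "IL1R1", "macrophage", "IL-iCAF"),
        ("PDGFB", "PDGFRB", "cancer", "myCAF"),
    ]
    return synth.gen_lri_outputs(trues, n_patients=6, noise_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def counts_truth():
    return synth.gen_scrnaseq_counts(
        n_cells_per_subset=50, n_genes=1000, markers_per_subset=25,
        effect_log2fc=2.0, seed=5,
    )
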