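import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from germsoma import CountMatrix, SimConfig, simulate_expression_counts

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_counts() -> CountMatrix:
    """Small three-condition count matrix with planted skn-1-dependent genes."""
    cfg = SimConfig(
        n_genes=400,
        n_replicates=3,
        library_size=2e5,
        germline_share=0.0,
        residual_germline=0.0,
        class_fractions={
            "somatic_specific": 0.3,
            "germline_specific": 0.0,
            "ubiquitous": 0.65,
            "gsc_induced": 0.0,
            "skn1_dependent": 0.05,
        },
        seed=42,
    )
    counts, _ = simulate_expression_counts(cfg)
    return counts


@pytest.fixture(scope="session")
def tiny_counts() -> CountMatrix:
    """Hand-sized 5-gene x 6-sample matrix for exact bookkeeping checks."""
    rng = np.random.default_rng(3)
    samples = pd.DataFrame(
        {
            "genotype": ["WT"] * 3 + ["GSC-"] * 3,
            "rnai": ["vector"] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    )
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(5, 6)),
        index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"),
        columns=samples.index,
    )
    return CountMatrix(counts, samples)
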