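import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from epinteg import (  # noqa: E402
    SimulationConfig,
    simulate_gene_models,
    simulate_paired_experiment,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=300, seed=11, concordance=1.0,
                            n_variants_in_da=8)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """One simulated paired experiment shared across read-only tests."""
    rna, atac, truth = simulate_paired_experiment(small_config)
    return rna, atac, truth


@pytest.fixture(scope="session")
def small_genome(small_config):
    genes, enhancers, links, templates = simulate_gene_models(small_config)
    return genes, enhancers, links, templates


@pytest.fixture()
def toy_counts():
    """3 genes x 4 samples with a 2-vs-2 design."""
    df = pd.DataFrame(
        {
            "A_r1": [5, 0, 12],
            "A_r2": [7, 0, 3],
            "B_r1": [6, 1, 9],
            "B_r2": [4, 2, 11],
        },
        index=["g1", "g2", "g3"],
    )
    from epinteg import CountMatrix

    return CountMatrix(
        df,
        {"A_r1": "A", "A_r2": "A", "B_r1": "B", "B_r2": "B"},
        {"A_r1": 1, "A_r2": 2, "B_r1": 1, "B_r2": 2},
    )
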