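import numpy as np
import pandas as pd
import pytest

import dese


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 6 tissues, 80 genes, 8 causal, planted driver T03."""
    return dese.SimulationConfig(
        seed=11, n_tissues=6, n_genes=80, n_causal=8, n_samples=200, driver_index=3
    )


@pytest.fixture(scope="session")
def small_pipeline(small_config):
    """Genotypes, panels, GWAS and gene-based scan for the small study."""
    panel, regions = dese.simulate_genotypes(small_config)
    tissue_panel, causal = dese.simulate_expression(small_config)
    celltype_panel, _ = dese.simulate_celltype_panel(small_config)
    gwas = dese.simulate_gwas(small_config, regions, causal)
    results, gene_data = dese.gene_based_scan(gwas, panel, regions)
    return {
        "config": small_config,
        "panel": panel,
        "regions": regions,
        "tissue_panel": tissue_panel,
        "celltype_panel": celltype_panel,
        "causal": causal,
        "gwas": gwas,
        "results": results,
        "gene_data": gene_data,
    }


@pytest.fixture
def toy_counts():
    """4 genes x 3 samples with distinct library sizes."""
    return pd.DataFrame(
        {
            "s1": [1, 3, 0, 4],
            "s2": [2, 6, 0, 8],
            "s3": [5, 5, 5, 5],
        },
        index=["g1", "g2", "g3", "g4"],
    )
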