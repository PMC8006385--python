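import numpy as np
import pandas as pd
import pytest

import otukit as ok


@pytest.fixture
def tiny_exp():
    """3 features x 4 samples with full taxonomy and mixed-type metadata."""
    counts = pd.DataFrame(
        [[6, 2, 0, 1], [4, 4, 3, 0], [0, 8, 5, 9]],
        index=["f1", "f2", "f3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    taxonomy = pd.DataFrame(
        {
            "superkingdom": ["Bacteria"] * 3,
            "phylum": ["Firmicutes", "Firmicutes", "Proteobacteria"],
            "genus": ["Streptococcus", "Streptococcus", "Moraxella"],
            "species": ["sp1", "sp2", "sp3"],
        },
        index=["f1", "f2", "f3"],
    )
    metadata = pd.DataFrame(
        {
            "group": ["case", "case", "control", "control"],
            "age": [31.0, 44.0, 52.0, 28.0],
        },
        index=["S1", "S2", "S3", "S4"],
    )
    return ok.create_experiment(counts, taxonomy=taxonomy, metadata=metadata)


@pytest.fixture(scope="session")
def effect_sim():
    """Moderate two-group experiment with 15% DA taxa at log2fc = 2."""
    config = ok.SimConfig(
        n_per_group=(12, 12), n_taxa=80, prop_da=0.15, log2fc=2.0,
        dispersion=0.2, seed=42,
    )
    return ok.simulate_experiment(config)


@pytest.fixture(scope="session")
def cluster_sim():
    """Two well-separated community clusters for beta-diversity surfaces."""
    config = ok.SimConfig(
        n_per_group=(10, 10), n_taxa=60, dispersion=0.2, seed=7,
    )
    return ok.simulate_two_cluster_profiles(config, divergence=0.9)
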