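import numpy as np
import pandas as pd
import pytest

from spikequant.io import (
    CountTable,
    RunConfig,
    SampleMetadata,
    SpikeInDesign,
    TaxonomyTable,
)
from spikequant.simulate import SimConfig, simulate_experiment


def make_metadata(sample_ids, r=0.5, v=2.0, lon_start=150.0, seed=0):
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    df = pd.DataFrame(
        {
            "temperature": np.linspace(28.6, 29.6, n),
            "salinity": np.linspace(33.7, 35.1, n),
            "nox": np.linspace(0.02, 0.1, n),
            "drp": np.linspace(0.02, 0.14, n),
            "silicate": np.linspace(0.6, 1.9, n),
            "chla": np.linspace(6.0, 48.0, n),
            "bacterial_abundance": np.linspace(1.2e5, 1.6e5, n),
            "longitude": ((np.linspace(lon_start, lon_start + 40, n) + 180) % 360) - 180,
            "latitude": np.linspace(10.0, 28.0, n) + rng.normal(0, 0.1, n),
            "recovery_ratio": np.full(n, r),
            "volume": np.full(n, v),
        },
        index=sample_ids,
    )
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def small_sim():
    """Moderate synthetic experiment shared by read-only tests."""
    cfg = SimConfig(n_samples=12, n_otus=200, depth=50_000, seed=11)
    community, metadata, counts, taxonomy, design = simulate_experiment(cfg)
    return {
        "cfg": cfg,
        "community": community,
        "metadata": metadata,
        "counts": counts,
        "taxonomy": taxonomy,
        "design": design,
    }


@pytest.fixture()
def toy_counts():
    return CountTable(
        pd.DataFrame(
            [[6, 4, 0], [2, 8, 1]],
            index=["S1", "S2"],
            columns=["O1", "O2", "O3"],
        )
    )


@pytest.fixture()
def run_config():
    return RunConfig(rng_seed=1, n_permutations=99)
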