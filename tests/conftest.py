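import numpy as np
import pandas as pd
import pytest

from poolscreen import (
    CountMatrix,
    LibraryDesign,
    PooledScreenModel,
    SampleSheet,
    SimConfig,
)


@pytest.fixture
def toy_counts() -> CountMatrix:
    rng = np.random.default_rng(7)
    counts = rng.integers(50, 500, size=(12, 4))
    guides = tuple(f"g{i:02d}" for i in range(12))
    return CountMatrix(guides, ("ctrl", "n14_t1", "n16_t1", "n18_t1"), counts)


@pytest.fixture
def toy_library(toy_counts) -> LibraryDesign:
    # 4 genes x 3 guides
    return LibraryDesign({g: f"GENE{i // 3}" for i, g in enumerate(toy_counts.guide_ids)})


@pytest.fixture
def toy_sheet() -> SampleSheet:
    df = pd.DataFrame(
        {
            "arm": ["control", "treated", "treated", "treated"],
            "concentration_uM": [0.0, 14.0, 16.0, 18.0],
            "timepoint": [0, 1, 1, 1],
        },
        index=pd.Index(["ctrl", "n14_t1", "n16_t1", "n18_t1"], name="sample_id"),
    )
    return SampleSheet(df)


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A fast small screen with clear signal for end-to-end tests."""
    return SimConfig(
        seed=42,
        n_genes=120,
        guides_per_gene=6,
        depth=400_000,
        population_size=400_000,
    )


@pytest.fixture(scope="session")
def small_fit(small_sim_config):
    model = PooledScreenModel.from_simulation(small_sim_config)
    return model, model.fit()
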