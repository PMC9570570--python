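"""Shared fixtures: small synthetic datasets and fast train configs.

All fixtures are generated programmatically and sized for speed; the
session scope keeps the expensive simulated datasets shared across tests.
"""

import numpy as np
import pandas as pd
import pytest

from specadapt import (
    TrainConfig,
    default_material_library,
    make_domain_split,
    simulate_domain_pair,
)
from specadapt.spectra_io import META_COLUMNS, SpectralDataset, sensor_grid


@pytest.fixture(scope="session")
def library():
    return default_material_library(seed=0)


@pytest.fixture(scope="session")
def domain_pair(library):
    """Small paired static/moving datasets: 25 units x 2 samples x 2
    replicates on the S2.0 grid (100 spectra per condition)."""
    return simulate_domain_pair(
        library, "medium", n_samples=2, n_replicates=2, sensor="S2.0", seed=7
    )


@pytest.fixture(scope="session")
def small_split(domain_pair):
    static, moving = domain_pair
    return make_domain_split(static, moving, n_labelled_per_unit=0, seed=3)


@pytest.fixture()
def fast_config():
    return TrainConfig(epochs=3, seed=5)


def toy_dataset(n=10, sensor="S2.0", material="oat flour", seed=0, domain="static"):
    """A hand-built dataset of random spectra of one material."""
    rng = np.random.default_rng(seed)
    grid = sensor_grid(sensor)
    meta = pd.DataFrame(
        {
            "material_id": material,
            "brand_id": 1,
            "allergen_class": "gluten",
            "domain_tag": domain,
            "sensor_tag": sensor,
            "sample_id": [1 + i // 2 for i in range(n)],
            "replicate_id": [1 + i % 2 for i in range(n)],
        },
        columns=list(META_COLUMNS),
    )
    return SpectralDataset(grid, rng.normal(0.5, 0.1, size=(n, len(grid))), meta)
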