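import numpy as np
import pandas as pd
import pytest

from histotme import (
    PlantedBagSpec,
    PlantedCohortSpec,
    default_registry,
    gen_bags,
    gen_cohort,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_bags():
    """A small planted-signal bag set for fast MIL unit tests."""
    spec = PlantedBagSpec(n_patients=24, tiles_range=(10, 30), dim=16, seed=42)
    return gen_bags(spec)


@pytest.fixture(scope="session")
def two_blob_cohort():
    """Two well-separated planted subtypes, 120 samples."""
    spec = PlantedCohortSpec(n_samples=120, separation=6.0, seed=5)
    return gen_cohort(spec)


@pytest.fixture(scope="session")
def planted_response_cohort():
    """400-sample cohort with a planted CM+Th2 interaction response effect."""
    spec = PlantedCohortSpec(n_samples=400, response_slope=2.0, seed=11)
    return gen_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_expression():
    """10 genes x 6 samples TPM matrix with fixed values."""
    r = np.random.default_rng(3)
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{j}" for j in range(6)]
    return pd.DataFrame(r.gamma(2.0, 50.0, size=(10, 6)), index=genes, columns=samples)
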