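import numpy as np
import pandas as pd
import pytest

from cortexdensity import AreaTimeDistribution, DensityTable, NeurogenesisParams


@pytest.fixture(scope="session")
def params() -> NeurogenesisParams:
    """Marmoset-calibrated model parameters."""
    return NeurogenesisParams.defaults()


@pytest.fixture(scope="session")
def dist() -> AreaTimeDistribution:
    """Marmoset-calibrated proliferation-time distribution."""
    return AreaTimeDistribution.defaults()


@pytest.fixture()
def small_table() -> DensityTable:
    return DensityTable(pd.DataFrame({
        "species": ["m", "m", "m"],
        "area_id": ["V1", "V2", "V3"],
        "sample_id": ["s1", "s2", "s3"],
        "density": [150000.0, 80000.0, 75000.0],
    }))


@pytest.fixture()
def lognormal_species_frame():
    """100 lognormal area densities for one synthetic species."""
    rng = np.random.default_rng(11)
    dens = np.exp(rng.normal(11.3, 0.3, size=100))
    return pd.DataFrame({
        "species": "synthetic",
        "area_id": [f"area{i:03d}" for i in range(100)],
        "sample_id": [f"area{i:03d}" for i in range(100)],
        "density": dens,
    })
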