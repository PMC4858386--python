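import numpy as np
import pandas as pd
import pytest

from dbpexposure import (
    ScenarioConfig,
    default_factors,
    simulate_monitoring,
    substitute_half_lod,
)


@pytest.fixture(scope="session")
def scenario():
    return ScenarioConfig(seed=20260101 % 2**31)


@pytest.fixture(scope="session")
def monitoring(scenario):
    """Half-LOD-substituted monitoring record shared across tests."""
    return substitute_half_lod(simulate_monitoring(scenario))


@pytest.fixture(scope="session")
def zones(monitoring):
    return sorted(monitoring["wsz_id"].unique())


@pytest.fixture(scope="session")
def factors():
    return default_factors()


def make_samples(values, below=None, lods=None, analyte="TTHM"):
    """Tiny monitoring frame from raw vectors."""
    n = len(values)
    below = below or [False] * n
    lods = lods if lods is not None else [np.nan] * n
    return pd.DataFrame({
        "wsz_id": ["WSZ1"] * n,
        "date": pd.to_datetime(["2008-06-15"] * n),
        "analyte": [analyte] * n,
        "value": values,
        "below_lod": below,
        "lod": lods,
        "conductivity": np.nan, "temperature": np.nan,
        "toc": np.nan, "total_chlorine": np.nan,
    })
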