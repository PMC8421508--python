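import math

import pandas as pd
import pytest

from weekmort import synthetic_data as sd


@pytest.fixture(scope="session")
def noise_free_sim():
    """Deterministic, season-free, trend-free synthetic series (2015-2020)."""
    cfg = sd.SimConfig(noise="none", seasonal_amplitude=0.0, trend=0.0, seed=0)
    return sd.generate(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Poisson-noise series with seasonality and a mild secular trend."""
    cfg = sd.SimConfig(seed=42)
    return sd.generate(cfg)


@pytest.fixture()
def annual_table(noise_free_sim):
    return noise_free_sim.annual


def group_series(values, groups=None):
    """Series indexed by age-group tuples (helper for harmonizer tests)."""
    if groups is None:
        groups = [(0, 65), (65, math.inf)][: len(values)]
    return pd.Series(
        [float(v) for v in values],
        index=pd.Index(list(groups), tupleize_cols=False),
    )
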