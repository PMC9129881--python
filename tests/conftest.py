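"""Shared fixtures.

The desk-scale experiment bundle (control / step-warming / step-and-cool /
four RCP scenarios × 3 repeats) is expensive, so it runs once per session
and is shared by every test that asserts on its dynamics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tundraline.climate import MonthlyClimateSeries
from tundraline.forcing import synth_instrumental
from tundraline.wind import synth_wind

# master seed of the desk experiment used across the dynamical tests
DESK_MASTER_SEED = 1


@pytest.fixture(scope="session")
def desk_bundle():
    """Full desk-scale experiment: 50-km transect, 600 years, 3 repeats."""
    from tundraline.experiment import DESK_PLAN, run_experiment

    return run_experiment(DESK_PLAN, master_seed=DESK_MASTER_SEED)


@pytest.fixture(scope="session")
def wind_df():
    return synth_wind(20_000, rng_seed=5)


@pytest.fixture()
def small_forcing():
    """6 nodes, 120 noisy years, 6 °C/100 km gradient."""
    return synth_instrumental(
        6, years=(1901, 2020), latitudinal_gradient=6.0, base_t_jul=11.0, rng_seed=3
    )


@pytest.fixture()
def flat_forcing():
    """Noise-free (exactly periodic) series for closed-form checks."""
    return synth_instrumental(
        15, years=(1951, 2050), latitudinal_gradient=1.0, base_t_jul=12.0,
        noise_scale=0.0, rng_seed=0,
    )


def constant_series(n_nodes, years, temp_c, precip_mm=20.0):
    """Series with every month at ``temp_c`` and ``precip_mm``."""
    y0, y1 = years
    n_years = y1 - y0 + 1
    return MonthlyClimateSeries(
        node_km=np.arange(n_nodes) * 10.0,
        years=np.arange(y0, y1 + 1),
        temp=np.full((n_nodes, n_years, 12), float(temp_c)),
        precip=np.full((n_nodes, n_years, 12), float(precip_mm)),
    )
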