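"""Synthetic wind forcing for ballistic seed dispersal.

Stand-in for a 6-hourly reanalysis wind record: speeds are Weibull
distributed (the standard surface-wind speed model) and transport bearings
von Mises distributed around a prevailing direction.  Directions follow
the meteorological bearing convention, degrees clockwise from north, and
denote the direction *toward* which seeds are carried.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["synth_wind", "weibull_mean"]


def weibull_mean(scale: float, shape: float) -> float:
    """Analytic mean of a Weibull(scale, shape) speed distribution."""
    return scale * math.gamma(1.0 + 1.0 / shape)


def synth_wind(
    n_samples: int,
    prevailing_direction: float = 45.0,
    weibull_scale: float = 5.0,
    weibull_shape: float = 2.0,
    concentration: float = 0.8,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Draw wind samples: columns ``speed_ms`` and ``direction_deg``.

    Parameters
    ----------
    prevailing_direction : float
        Mean transport bearing, degrees from north in [0, 360).
    weibull_scale, weibull_shape : float
        Weibull speed parameters (m/s; shape 2 is a Rayleigh-like wind).
    concentration : float
        Von Mises concentration of the bearing; larger is narrower.
    """
    rng = np.random.default_rng(rng_seed)
    speed = weibull_scale * rng.weibull(weibull_shape, size=n_samples)
    if concentration <= 0:
        dirs = rng.uniform(0.0, 360.0, size=n_samples)
    else:
        dirs = (prevailing_direction + np.degrees(rng.vonmises(0.0, concentration, size=n_samples))) % 360.0
    return pd.DataFrame({"speed_ms": speed, "direction_deg": dirs})
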