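"""Annual climate auxiliaries derived from monthly series.

The simulator's growth, establishment and mortality responses are driven by
a handful of annual summaries per climate node:

* ``t_jan`` / ``t_jul`` — coldest- and warmest-month temperature (°C),
* ``ndd0`` — net degree days: sum of daily mean temperatures above 0 °C,
* ``aat10`` — active air temperature: sum of daily temperatures on days
  exceeding 10 °C,
* ``p_year`` — annual precipitation (mm),
* ``drought_index`` — annual precipitation over growing-season degree days.

Daily temperatures are obtained by linear interpolation between mid-month
anchor values with periodic wrap across the year boundary; the degree-day
sums are then exact sums over the 365 interpolated days.  The whole
transformation is a fixed linear map from the 12 monthly values to 365
daily values, precomputed once as a (365, 12) weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClimateAuxiliaries", "daily_from_monthly", "auxiliary_table", "derive_auxiliaries"]

_MONTH_LEN = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
_DAYS = 365


def _daily_weight_matrix() -> np.ndarray:
    """(365, 12) matrix W with daily[d] = sum_m W[d, m] * monthly[m].

    Anchors sit at the mid-day of each month; between anchors the daily
    value is the linear interpolant, wrapping Dec→Jan periodically.
    """
    starts = np.concatenate([[0.0], np.cumsum(_MONTH_LEN)[:-1]])
    mids = starts + (_MONTH_LEN - 1) / 2.0  # day-of-year of each anchor (0-based)
    W = np.zeros((_DAYS, 12))
    for d in range(_DAYS):
        # locate flanking anchors on the periodic year
        if d < mids[0]:
            m0, m1 = 11, 0
            span = (mids[0] + _DAYS) - mids[11]
            frac = (d + _DAYS - mids[11]) / span
        elif d >= mids[-1]:
            m0, m1 = 11, 0
            span = (mids[0] + _DAYS) - mids[11]
            frac = (d - mids[11]) / span
        else:
            m0 = int(np.searchsorted(mids, d, side="right")) - 1
            m1 = m0 + 1
            span = mids[m1] - mids[m0]
            frac = (d - mids[m0]) / span
        W[d, m0] += 1.0 - frac
        W[d, m1] += frac
    return W


_W_DAILY = _daily_weight_matrix()


@dataclass(frozen=True)
class ClimateAuxiliaries:
    t_jan: float
    t_jul: float
    ndd0: float
    aat10: float
    p_year: float
    drought_index: float


def daily_from_monthly(monthly: np.ndarray) -> np.ndarray:
    """Interpolate monthly values (last axis length 12) to 365 daily values."""
    monthly = np.asarray(monthly, dtype=float)
    return monthly @ _W_DAILY.T


def auxiliary_table(series) -> dict[str, np.ndarray]:
    """All auxiliaries for every (node, year) of a MonthlyClimateSeries.

    Returns a dict of (n_nodes, n_years) arrays keyed by auxiliary name.
    """
    daily = daily_from_monthly(series.temp)  # (nodes, years, 365)
    ndd0 = np.clip(daily, 0.0, None).sum(axis=-1)
    aat10 = np.where(daily > 10.0, daily, 0.0).sum(axis=-1)
    p_year = series.annual_precip()
    return {
        "t_jan": series.january(),
        "t_jul": series.july(),
        "ndd0": ndd0,
        "aat10": aat10,
        "p_year": p_year,
        "drought_index": p_year / np.maximum(ndd0, 1.0),
    }


def derive_auxiliaries(series, node_km: float, year: int) -> ClimateAuxiliaries:
    """Auxiliaries for a single node and year."""
    ni = int(np.argmin(np.abs(series.node_km - node_km)))
    if abs(series.node_km[ni] - node_km) > 1e-6:
        raise KeyError(f"no climate node at {node_km} km")
    yi = series.year_index(year)
    daily = daily_from_monthly(series.temp[ni, yi])
    ndd0 = float(np.clip(daily, 0.0, None).sum())
    aat10 = float(np.where(daily > 10.0, daily, 0.0).sum())
    p_year = float(series.precip[ni, yi].sum())
    return ClimateAuxiliaries(
        t_jan=float(series.temp[ni, yi, 0]),
        t_jul=float(series.temp[ni, yi, 6]),
        ndd0=ndd0,
        aat10=aat10,
        p_year=p_year,
        drought_index=p_year / max(ndd0, 1.0),
    )
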