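"""Monthly climate series container for latitudinal transects.

The forcing that drives the treeline simulator is a per-node monthly series
of air temperature (°C) and precipitation (mm).  Nodes are spaced every
10 km along a transect, ``node_km = 0`` at the treeline-side start and
increasing poleward toward the Arctic shoreline.

Internally the series is a dense ``(n_nodes, n_years, 12)`` array pair,
which keeps year/month bookkeeping trivial and makes the derived annual
auxiliaries (degree-day sums etc.) cheap to vectorise.  Tidy tabular I/O
(``node_km, year, month, temp_C, precip_mm``) is provided for interchange,
plus an xarray bridge for self-describing bulk storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NODE_SPACING_KM = 10.0

__all__ = ["MonthlyClimateSeries", "NODE_SPACING_KM", "concat_years"]


@dataclass
class MonthlyClimateSeries:
    """Per-node monthly temperature and precipitation over contiguous years.

    Parameters
    ----------
    node_km : (n_nodes,) float array
        Along-transect node positions in km; must be spaced 10 km apart.
    years : (n_years,) int array
        Contiguous calendar years (CE).
    temp : (n_nodes, n_years, 12) float array
        Monthly mean temperature, °C.
    precip : (n_nodes, n_years, 12) float array
        Monthly precipitation sum, mm (non-negative).
    """

    node_km: np.ndarray
    years: np.ndarray
    temp: np.ndarray
    precip: np.ndarray

    def __post_init__(self) -> None:
        self.node_km = np.asarray(self.node_km, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.temp = np.asarray(self.temp, dtype=float)
        self.precip = np.asarray(self.precip, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        n_nodes, n_years = len(self.node_km), len(self.years)
        if self.temp.shape != (n_nodes, n_years, 12):
            raise ValueError(
                f"temp shape {self.temp.shape} != {(n_nodes, n_years, 12)}"
            )
        if self.precip.shape != self.temp.shape:
            raise ValueError("precip shape differs from temp shape")
        if n_years > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be contiguous and increasing")
        if n_nodes > 1:
            spacing = np.diff(self.node_km)
            if not np.allclose(spacing, NODE_SPACING_KM):
                raise ValueError("node spacing must be exactly 10 km")
        if np.any(self.precip < -1e-9):
            raise ValueError("precipitation must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_km)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        i = int(year) - int(self.years[0])
        if i < 0 or i >= self.n_years:
            raise KeyError(f"year {year} outside {self.years[0]}–{self.years[-1]}")
        return i

    # -- derived views -----------------------------------------------------

    def july(self) -> np.ndarray:
        """July temperature, shape (n_nodes, n_years)."""
        return self.temp[:, :, 6]

    def january(self) -> np.ndarray:
        return self.temp[:, :, 0]

    def annual_mean_temp(self) -> np.ndarray:
        return self.temp.mean(axis=2)

    def annual_precip(self) -> np.ndarray:
        return self.precip.sum(axis=2)

    def slice_years(self, start: int, stop: int) -> "MonthlyClimateSeries":
        """Inclusive year slice [start, stop]."""
        i0, i1 = self.year_index(start), self.year_index(stop)
        return MonthlyClimateSeries(
            node_km=self.node_km.copy(),
            years=self.years[i0 : i1 + 1].copy(),
            temp=self.temp[:, i0 : i1 + 1].copy(),
            precip=self.precip[:, i0 : i1 + 1].copy(),
        )

    def copy(self) -> "MonthlyClimateSeries":
        return MonthlyClimateSeries(
            self.node_km.copy(), self.years.copy(), self.temp.copy(), self.precip.copy()
        )

    # -- tidy tabular I/O --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        nodes, years, months = np.meshgrid(
            self.node_km, self.years, np.arange(1, 13), indexing="ij"
        )
        return pd.DataFrame(
            {
                "node_km": nodes.ravel(),
                "year": years.ravel().astype(int),
                "month": months.ravel().astype(int),
                "temp_C": self.temp.ravel(),
                "precip_mm": self.precip.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MonthlyClimateSeries":
        node_km = np.sort(df["node_km"].unique())
        years = np.sort(df["year"].unique()).astype(int)
        if not np.all(np.diff(years) == 1):
            raise ValueError("years in table are not contiguous")
        shape = (len(node_km), len(years), 12)
        temp = np.full(shape, np.nan)
        precip = np.full(shape, np.nan)
        ni = pd.Index(node_km).get_indexer(df["node_km"])
        yi = df["year"].to_numpy(dtype=int) - years[0]
        mi = df["month"].to_numpy(dtype=int) - 1
        temp[ni, yi, mi] = df["temp_C"].to_numpy()
        precip[ni, yi, mi] = df["precip_mm"].to_numpy()
        if np.isnan(temp).any() or np.isnan(precip).any():
            raise ValueError("table has gaps: every (node, year, month) required")
        return cls(node_km=node_km, years=years, temp=temp, precip=precip)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MonthlyClimateSeries":
        return cls.from_frame(pd.read_csv(path))

    # -- gridded self-describing I/O --------------------------------------

    def to_dataset(self):
        import xarray as xr

        return xr.Dataset(
            {
                "temp_C": (("node_km", "year", "month"), self.temp),
                "precip_mm": (("node_km", "year", "month"), self.precip),
            },
            coords={
                "node_km": self.node_km,
                "year": self.years,
                "month": np.arange(1, 13),
            },
        )

    @classmethod
    def from_dataset(cls, ds) -> "MonthlyClimateSeries":
        return cls(
            node_km=np.asarray(ds["node_km"]),
            years=np.asarray(ds["year"]),
            temp=np.asarray(ds["temp_C"]),
            precip=np.asarray(ds["precip_mm"]),
        )


def concat_years(*parts: MonthlyClimateSeries) -> MonthlyClimateSeries:
    """Concatenate series along the year axis; spans must abut without gaps."""
    parts = sorted(parts, key=lambda s: s.years[0])
    for a, b in zip(parts, parts[1:]):
        if b.years[0] != a.years[-1] + 1:
            raise ValueError(
                f"year spans not contiguous: {a.years[-1]} then {b.years[0]}"
            )
        if not np.allclose(a.node_km, b.node_km):
            raise ValueError("node positions differ between parts")
    return MonthlyClimateSeries(
        node_km=parts[0].node_km.copy(),
        years=np.concatenate([p.years for p in parts]),
        temp=np.concatenate([p.temp for p in parts], axis=1),
        precip=np.concatenate([p.precip for p in parts], axis=1),
    )
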