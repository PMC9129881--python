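"""Stand metrics: density profiles, treeline positions, migration rates,
climate-analogue tracking and lag/overshoot trajectories.

Definitions (stand density counted in *stems*, trees taller than 1.3 m):

* **single-tree stand** — the northernmost position anywhere with
  ≥ 1 stem ha⁻¹;
* **treeline stand** — the northern edge of the contiguous run of bins
  with ≥ 1 stem ha⁻¹ that is connected to the southern (forested)
  boundary;
* **forestline stand** — the northernmost position with > 100 stems ha⁻¹.

The **climate-analogue** position is where the current (10-year-smoothed)
July temperature equals the July temperature at the baseline treeline: its
motion is the climatic velocity the simulated treeline is compared
against.  A trajectory point below the diagonal (simulated behind the
analogue) is migration lag; above is overshoot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandDensityProfile",
    "TreelineRecord",
    "TrajectoryPoint",
    "density_profile",
    "extract_positions",
    "analogue_track",
    "migration_rates",
    "lag_trajectory",
    "equilibrium_crossing_year",
]

STEM_HEIGHT_M = 1.3
TREELINE_MIN_STEMS_HA = 1.0
FORESTLINE_MIN_STEMS_HA = 100.0


@dataclass
class StandDensityProfile:
    year: int
    bin_start_km: np.ndarray
    bin_length_km: float
    stems_per_ha: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "bin_start_km": self.bin_start_km,
                "bin_length_km": self.bin_length_km,
                "stems_per_ha": self.stems_per_ha,
            }
        )


@dataclass(frozen=True)
class TreelineRecord:
    year: int
    single_tree_km: float | None
    treeline_km: float | None
    forestline_km: float | None


@dataclass(frozen=True)
class TrajectoryPoint:
    period_start_year: int
    simulated_fraction: float
    analogue_fraction: float


def density_profile(
    y_m,
    height_m,
    transect_length_km: float,
    width_m: float,
    bin_length_km: float = 1.0,
    year: int = 0,
) -> StandDensityProfile:
    """Stems-per-hectare along the transect in fixed bins.

    Bins are half-open ``[start, start + bin_length)`` south-inclusive and
    tile the transect; density divides the stem count by the bin area
    ``bin_length·width`` in hectares.
    """
    if bin_length_km <= 0:
        raise ValueError("bin_length_km must be positive")
    y = np.asarray(y_m, dtype=float)
    h = np.asarray(height_m, dtype=float)
    stems_y = y[h > STEM_HEIGHT_M]
    n_bins = int(np.ceil(transect_length_km / bin_length_km))
    edges_km = np.arange(n_bins + 1) * bin_length_km
    counts, _ = np.histogram(stems_y / 1000.0, bins=edges_km)
    area_ha = bin_length_km * 1000.0 * width_m / 1e4
    return StandDensityProfile(
        year=year,
        bin_start_km=edges_km[:-1],
        bin_length_km=bin_length_km,
        stems_per_ha=counts / area_ha,
    )


def extract_positions(profile: StandDensityProfile) -> TreelineRecord:
    """Single-tree / treeline / forestline positions from a density profile.

    Positions are the northern edge of the qualifying bin.  With no bin at
    ≥ 1 stem ha⁻¹ all three are None (explicitly absent, not zero).
    """
    d = np.asarray(profile.stems_per_ha, dtype=float)
    starts = np.asarray(profile.bin_start_km, dtype=float)
    L = profile.bin_length_km
    occupied = d >= TREELINE_MIN_STEMS_HA
    if not occupied.any():
        return TreelineRecord(profile.year, None, None, None)

    single_tree = float(starts[np.nonzero(occupied)[0][-1]] + L)

    if occupied[0]:
        run_end = int(np.argmin(occupied)) - 1 if not occupied.all() else len(d) - 1
        treeline = float(starts[run_end] + L)
    else:
        treeline = None

    dense = d > FORESTLINE_MIN_STEMS_HA
    forestline = float(starts[np.nonzero(dense)[0][-1]] + L) if dense.any() else None
    return TreelineRecord(profile.year, single_tree, treeline, forestline)


def analogue_track(
    forcing,
    baseline_year: int,
    baseline_treeline_km: float,
    years=None,
    shoreline_km: float | None = None,
    smooth_years: int = 10,
) -> pd.DataFrame:
    """Track the position where smoothed July temperature matches the
    baseline treeline's July temperature.

    Per year the northernmost along-transect position with 10-year trailing
    mean July temperature ≥ the baseline value is found by linear
    interpolation between climate nodes, clamped to [0, shoreline].
    Returns a DataFrame with columns ``year`` and ``analogue_km``.
    """
    node_km = np.asarray(forcing.node_km, dtype=float)
    if shoreline_km is None:
        shoreline_km = float(node_km[-1])
    july = forcing.july()  # (nodes, years)
    # trailing mean over years
    sm = np.empty_like(july)
    c = np.cumsum(july, axis=1)
    for i in range(july.shape[1]):
        lo = max(0, i - smooth_years + 1)
        total = c[:, i] - (c[:, lo - 1] if lo > 0 else 0.0)
        sm[:, i] = total / (i - lo + 1)

    bi = forcing.year_index(baseline_year)
    t0 = float(np.interp(baseline_treeline_km, node_km, sm[:, bi]))

    if years is None:
        years = forcing.years
    out = np.empty(len(years))
    for k, yr in enumerate(years):
        prof = sm[:, forcing.year_index(int(yr))]
        out[k] = _northernmost_at_least(node_km, prof, t0)
    return pd.DataFrame({"year": np.asarray(years, dtype=int), "analogue_km": np.clip(out, 0.0, shoreline_km)})


def _northernmost_at_least(node_km: np.ndarray, temps: np.ndarray, t0: float) -> float:
    """Northernmost position where temps ≥ t0, by segment-wise linear
    interpolation; scan segments from the north end."""
    if temps[-1] >= t0:
        return float(node_km[-1]) + 1e9  # beyond the last node: clamp upstream
    for i in range(len(node_km) - 2, -1, -1):
        a, b = temps[i], temps[i + 1]
        if a >= t0 > b:
            frac = (a - t0) / (a - b)
            return float(node_km[i] + frac * (node_km[i + 1] - node_km[i]))
        if a >= t0 and b >= t0:  # unreachable given scan order; kept for safety
            return float(node_km[i + 1])
    return 0.0


def migration_rates(records: list[TreelineRecord], baseline_year: int = 2000) -> pd.DataFrame:
    """Decadal migration rates and cumulative advance relative to baseline.

    ``rate_km_per_decade(t) = position(t) − position(t−10)``; records must
    be at 10-year spacing and include the baseline year.
    """
    rows = [(r.year, r.treeline_km) for r in records]
    df = pd.DataFrame(rows, columns=["year", "treeline_km"]).sort_values("year")
    if baseline_year not in set(df["year"]):
        raise ValueError(f"no record at baseline year {baseline_year}")
    base = df.loc[df["year"] == baseline_year, "treeline_km"].iloc[0]
    if base is None or (isinstance(base, float) and np.isnan(base)):
        raise ValueError("treeline absent at the baseline year")
    pos = df["treeline_km"].astype(float).to_numpy()
    rate = np.full(len(pos), np.nan)
    rate[1:] = np.diff(pos)
    df["rate_km_per_decade"] = rate
    df["advance_km"] = pos - float(base)
    return df.reset_index(drop=True)


def lag_trajectory(
    records: list[TreelineRecord],
    analogue: pd.DataFrame,
    shoreline_km: float,
    current_km: float,
    segment_years: int = 25,
) -> list[TrajectoryPoint]:
    """Simulated-vs-analogue trajectory in scaled coordinates.

    Both positions are rescaled to fractions of the corridor between the
    current (baseline) treeline and the shoreline, clipped to [0, 1], then
    averaged in ``segment_years`` segments.  A point below the diagonal is
    migration lag; above it, overshoot.
    """
    if shoreline_km == current_km:
        raise ValueError("shoreline and current treeline coincide: no corridor")
    span = shoreline_km - current_km
    sim = pd.DataFrame(
        [(r.year, r.treeline_km) for r in records if r.treeline_km is not None],
        columns=["year", "sim_km"],
    )
    merged = sim.merge(analogue, on="year", how="inner")
    if merged.empty:
        return []
    y0 = int(merged["year"].min())
    seg = (merged["year"] - y0) // segment_years
    merged["sim_frac"] = np.clip((merged["sim_km"] - current_km) / span, 0.0, 1.0)
    merged["ana_frac"] = np.clip((merged["analogue_km"] - current_km) / span, 0.0, 1.0)
    out = []
    for s, grp in merged.groupby(seg):
        out.append(
            TrajectoryPoint(
                period_start_year=int(y0 + s * segment_years),
                simulated_fraction=float(grp["sim_frac"].mean()),
                analogue_fraction=float(grp["ana_frac"].mean()),
            )
        )
    return out


def equilibrium_crossing_year(trajectory: list[TrajectoryPoint]) -> int | None:
    """Start-year of the first segment where the simulated treeline has
    caught up with (or passed) its climate analogue after the initial lag
    phase; None if it lags forever.

    A trajectory that sits on or above the diagonal from the start (no lag
    phase at all) returns the first segment's year.
    """
    for pt in trajectory:
        if pt.simulated_fraction >= pt.analogue_fraction:
            return pt.period_start_year
    return None
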