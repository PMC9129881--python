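"""Tundra-area accounting along a treeline polyline.

Per-region treeline advances (km, from the transect simulations) are
interpolated along the circum-regional treeline polyline at 10-km arc
stations, turned into a poleward forest-extent polygon, and differenced
against the tundra portion of the land polygon.  All coordinates are
planar km in an equal-area projection applied upstream; this module never
reprojects.

The forest extent is recomputed from the current advances at every output
step (no running union), so tundra can partly recover when advances
shrink under cooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon, MultiPolygon
from shapely.ops import unary_union

__all__ = [
    "TreelineGeometry",
    "synth_geometry",
    "interpolate_advance",
    "forest_extent",
    "tundra_series",
]

log = logging.getLogger(__name__)

_FAR_KM = 1e5  # effectively infinite poleward depth for region strips


@dataclass
class TreelineGeometry:
    """Treeline polyline + land polygon + per-region transect anchors.

    ``anchor_arc_km`` are arc-length positions of the four transect anchor
    points along the polyline; region boundaries sit at the arc midpoints
    between consecutive anchors, end regions extending to the polyline
    ends.  ``poleward`` is a hint (unit vector) for which side of the
    polyline is tundra.
    """

    treeline: LineString
    coastline: Polygon
    anchor_arc_km: np.ndarray
    region_names: tuple[str, ...]
    poleward: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        self.anchor_arc_km = np.asarray(self.anchor_arc_km, dtype=float)
        if len(self.anchor_arc_km) != len(self.region_names):
            raise ValueError("one anchor per region required")

    @property
    def arc_length_km(self) -> float:
        return float(self.treeline.length)

    def tundra_polygon(self) -> Polygon:
        """Land on the poleward side of the treeline."""
        half = _band_polygon_arcspan(
            self.treeline, 0.0, self.arc_length_km, 0.0, _FAR_KM, self.poleward
        )
        return self.coastline.intersection(half)

    def region_bounds_km(self) -> np.ndarray:
        """Arc-length boundaries of the regions (len = n_regions + 1)."""
        a = self.anchor_arc_km
        mids = (a[:-1] + a[1:]) / 2.0
        return np.concatenate([[0.0], mids, [self.arc_length_km]])

    def region_polygon(self, i: int) -> Polygon:
        b = self.region_bounds_km()
        return self.tundra_polygon().intersection(
            _band_polygon_arcspan(self.treeline, b[i], b[i + 1], 0.0, _FAR_KM, self.poleward)
        )


def synth_geometry(
    corridor_width_km: float = 100.0,
    corridor_length_km: float = 500.0,
    n_regions: int = 4,
    curve_amplitude_km: float = 0.0,
    rng_seed: int = 0,
) -> TreelineGeometry:
    """Synthetic rectangular-corridor geometry with an optionally curved
    treeline; the analytic tundra area enables closed-form tests.

    The land polygon is the rectangle [0, width] × [0, length]; the
    treeline runs along y = amplitude·sin(πx/width) near the southern edge
    and tundra lies poleward (+y).
    """
    if corridor_width_km <= 0 or corridor_length_km <= 0:
        raise ValueError("corridor dimensions must be positive")
    rng = np.random.default_rng(rng_seed)
    W, L = corridor_width_km, corridor_length_km
    land = Polygon([(0, 0), (W, 0), (W, L), (0, L)])
    n_pts = 101
    xs = np.linspace(0.0, W, n_pts)
    ys = curve_amplitude_km * np.sin(np.pi * xs / W)
    treeline = LineString(np.column_stack([xs, ys]))
    # anchors at arc fractions (2i+1)/(2n): one per region, equidistant
    total = treeline.length
    fractions = (2 * np.arange(n_regions) + 1) / (2 * n_regions)
    anchors = fractions * total
    names = tuple(f"region_{i + 1}" for i in range(n_regions))
    del rng  # geometry is deterministic; seed kept for interface symmetry
    return TreelineGeometry(
        treeline=treeline,
        coastline=land,
        anchor_arc_km=anchors,
        region_names=names,
        poleward=(0.0, 1.0),
    )


def interpolate_advance(
    geometry: TreelineGeometry, anchor_advances, step_km: float = 10.0
) -> pd.DataFrame:
    """Advance at every 10-km arc station by inverse-arc-distance weighting
    of the two flanking anchors; end stations take the nearest anchor.

    Returns a DataFrame with columns ``station_arc_km`` and ``advance_km``.
    """
    adv = np.asarray(anchor_advances, dtype=float)
    if len(adv) != len(geometry.anchor_arc_km):
        raise ValueError("one advance per anchor required")
    total = geometry.arc_length_km
    stations = np.arange(0.0, total + step_km / 2.0, step_km)
    stations[-1] = min(stations[-1], total)
    out = np.interp(stations, geometry.anchor_arc_km, adv)  # linear == inverse-distance of 2 anchors
    return pd.DataFrame({"station_arc_km": stations, "advance_km": out})


def _station_points_normals(treeline: LineString, arcs: np.ndarray, poleward) -> tuple[np.ndarray, np.ndarray]:
    pts = np.array([treeline.interpolate(float(a)).coords[0] for a in arcs])
    # tangent by finite difference of neighbouring station points
    tang = np.gradient(pts, axis=0)
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])
    lens = np.linalg.norm(norm, axis=1)
    lens[lens == 0] = 1.0
    norm /= lens[:, None]
    pole = np.asarray(poleward, dtype=float)
    flip = (norm @ pole) < 0
    norm[flip] *= -1.0
    return pts, norm


def _band_polygon_arcspan(
    treeline: LineString, a0: float, a1: float, d0: float, d1: float, poleward
) -> Polygon:
    n = max(2, int(np.ceil((a1 - a0) / 5.0)) + 1)
    arcs = np.linspace(a0, a1, n)
    pts, norm = _station_points_normals(treeline, arcs, poleward)
    lo = pts + norm * d0
    hi = pts + norm * d1
    ring = np.vstack([lo, hi[::-1]])
    return Polygon(ring).buffer(0)


def forest_extent(geometry: TreelineGeometry, station_advances: pd.DataFrame) -> Polygon:
    """Poleward forest-extent polygon for the given station advances.

    Consecutive stations span quadrilaterals reaching from the treeline to
    the linearly interpolated advance along the local poleward normal;
    their union, clipped to the tundra polygon, is the forested extent.
    Zero-advance spans contribute nothing.
    """
    arcs = station_advances["station_arc_km"].to_numpy(dtype=float)
    adv = np.clip(station_advances["advance_km"].to_numpy(dtype=float), 0.0, None)
    pts, norm = _station_points_normals(geometry.treeline, arcs, geometry.poleward)
    quads = []
    for i in range(len(arcs) - 1):
        if adv[i] <= 0 and adv[i + 1] <= 0:
            continue
        p0, p1 = pts[i], pts[i + 1]
        q0 = p0 + norm[i] * adv[i]
        q1 = p1 + norm[i + 1] * adv[i + 1]
        poly = Polygon([tuple(p0), tuple(p1), tuple(q1), tuple(q0)])
        if not poly.is_valid:
            poly = poly.buffer(0)
        if not poly.is_empty:
            quads.append(poly)
    if not quads:
        return Polygon()
    union = unary_union(quads)
    if not union.is_valid:  # repaired by zero-buffer cleanup
        log.warning("forest extent union invalid; repairing with zero buffer")
        union = union.buffer(0)
    return union.intersection(geometry.tundra_polygon())


def tundra_series(
    geometry: TreelineGeometry,
    advances_by_year: dict[int, np.ndarray] | pd.DataFrame,
    step_km: float = 10.0,
) -> pd.DataFrame:
    """Remaining tundra area per region (and total) per output year.

    ``advances_by_year`` maps year → per-anchor advances (km); a tidy
    DataFrame with columns (year, region, advance_km) is also accepted.
    Extent is recomputed from each year's advances, so area can recover
    when advances decrease.  Returns tidy columns
    (year, region, area_km2, fraction_of_initial).
    """
    if isinstance(advances_by_year, pd.DataFrame):
        piv = advances_by_year.pivot(index="year", columns="region", values="advance_km")
        piv = piv[list(geometry.region_names)]
        advances_by_year = {int(y): piv.loc[y].to_numpy(dtype=float) for y in piv.index}

    regions = list(geometry.region_names)
    region_polys = [geometry.region_polygon(i) for i in range(len(regions))]
    init_areas = np.array([rp.area for rp in region_polys])
    if init_areas.sum() <= 0:
        raise ValueError("initial tundra area must be positive")

    rows = []
    for year in sorted(advances_by_year):
        stations = interpolate_advance(geometry, advances_by_year[year], step_km=step_km)
        forest = forest_extent(geometry, stations)
        for name, rp, a0 in zip(regions, region_polys, init_areas):
            lost = forest.intersection(rp).area if not forest.is_empty else 0.0
            remaining = max(a0 - lost, 0.0)
            rows.append((year, name, remaining, remaining / a0 if a0 > 0 else np.nan))
        total_lost = forest.area if not forest.is_empty else 0.0
        total_rem = max(init_areas.sum() - total_lost, 0.0)
        rows.append((year, "total", total_rem, total_rem / init_areas.sum()))
    return pd.DataFrame(rows, columns=["year", "region", "area_km2", "fraction_of_initial"])
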