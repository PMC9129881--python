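"""Individual-based larch life-cycle simulator on a wrapped 2-D transect.

Each simulated year invokes, in order: environment update (competition
density field and active-layer depth), growth, seed dispersal, seed
production, establishment, mortality, and ageing.  The transect is a
narrow strip ``transect_length_km`` long (y, metres, increasing poleward)
and ``transect_width_m`` wide (x); x wraps periodically at the east–west
margins, y does not — the strip represents a slice of a continuous
treeline.

Trees and seeds are stored as structure-of-arrays (numpy), and the yearly
density-field deposition runs through a numba kernel; everything else is
vectorised.  All stochastic processes draw from named, label-derived RNG
streams so that a master seed fully determines the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .auxiliaries import auxiliary_table
from .climate import MonthlyClimateSeries
from .params import LifeCycleParams, SimulationConfig

__all__ = [
    "EnvironmentState",
    "StandSnapshot",
    "SimulationResult",
    "TreelineSimulator",
    "run_simulation",
    "compute_max_growth",
    "tree_height",
    "breast_height_diameter",
    "competition_factor",
    "grow_trees",
    "interpolate_node_climate",
    "disperse_seeds",
    "produce_seeds",
    "establishment_probability",
    "tree_death_probability",
    "influence_radius",
    "density_field",
]


# ---------------------------------------------------------------------------
# response surfaces
# ---------------------------------------------------------------------------


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def compute_max_growth(t_jul, ndd0, params: LifeCycleParams):
    """Potential basal-diameter increment (cm/yr) from 10-yr mean climate.

    Smooth and non-decreasing in both July temperature and NDD0, saturating
    at ``g_max_cm`` on the warm plateau and identically zero below the cold
    threshold ``t_jul_cold``.
    """
    t_jul = np.asarray(t_jul, dtype=float)
    ndd0 = np.asarray(ndd0, dtype=float)
    f_t = _logistic((t_jul - params.t_jul_half) / params.t_jul_scale)
    f_n = _logistic((ndd0 - params.ndd_half) / params.ndd_scale)
    g = params.g_max_cm * f_t * f_n
    return np.where(t_jul < params.t_jul_cold, 0.0, g)


def tree_height(basal_cm, params: LifeCycleParams):
    """Saturating height–diameter allometry: h = h_max·(1 − exp(−k·d))."""
    return params.height_max_m * (1.0 - np.exp(-params.allom_k * np.asarray(basal_cm, dtype=float)))


def breast_height_diameter(basal_cm, height_m, params: LifeCycleParams):
    """Diameter at 1.3 m for a linearly tapering stem; 0 until height > 1.3 m."""
    h = np.asarray(height_m, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        taper = np.where(h > params.breast_height_m, 1.0 - params.breast_height_m / np.maximum(h, 1e-9), 0.0)
    return np.asarray(basal_cm, dtype=float) * taper


def competition_factor(density_index, params: LifeCycleParams):
    """Growth reduction in (0, 1], decreasing in the density index."""
    return 1.0 / (1.0 + params.comp_growth * np.asarray(density_index, dtype=float))


def grow_trees(basal_cm, max_growth, density_index, params: LifeCycleParams):
    """Apply one year's growth: basal increment = potential growth times
    the competition reduction factor; diameters never shrink."""
    inc = np.asarray(max_growth, dtype=float) * competition_factor(density_index, params)
    return np.asarray(basal_cm, dtype=float) + np.clip(inc, 0.0, None)


def influence_radius(height_m, params: LifeCycleParams):
    return np.minimum(
        params.influence_r0_m + params.influence_r_per_h * np.asarray(height_m, dtype=float),
        params.influence_r_max_m,
    )


# ---------------------------------------------------------------------------
# environment: competition density field + active layer
# ---------------------------------------------------------------------------


@njit(cache=True)
def _deposit(field, xs, ys, basal, radius, cell):  # pragma: no cover - numba
    ny, nx = field.shape
    for i in range(xs.shape[0]):
        r = radius[i]
        rc = int(r / cell) + 1
        cxi = int(xs[i] / cell)
        cyi = int(ys[i] / cell)
        iy0 = cyi - rc
        if iy0 < 0:
            iy0 = 0
        iy1 = cyi + rc
        if iy1 > ny - 1:
            iy1 = ny - 1
        for iy in range(iy0, iy1 + 1):
            dy = (iy + 0.5) * cell - ys[i]
            for ix in range(cxi - rc, cxi + rc + 1):
                dx = (ix + 0.5) * cell - xs[i]
                d = (dx * dx + dy * dy) ** 0.5
                w = 1.0 - d / r
                if w > 0.0:
                    jx = ix % nx
                    field[iy, jx] += basal[i] * w


@dataclass
class EnvironmentState:
    """Yearly gridded competition map plus per-node thaw depth."""

    density_field: np.ndarray  # (ny, nx) float32, basal-diameter-weighted influence
    cell_m: float
    active_layer_depth: np.ndarray  # per climate node, cm
    edaphic_factor: float

    def sample(self, x_m, y_m):
        """Field value at positions (nearest-cell lookup, x wrapped)."""
        ny, nx = self.density_field.shape
        ix = (np.asarray(x_m) / self.cell_m).astype(np.int64) % nx
        iy = np.clip((np.asarray(y_m) / self.cell_m).astype(np.int64), 0, ny - 1)
        return self.density_field[iy, ix].astype(float)


def density_field(
    x_m, y_m, basal_cm, height_m, params: LifeCycleParams, width_m: float, length_m: float,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Build the competition field: each tree deposits a triangular kernel
    of peak ``basal_cm`` and radius proportional to its height."""
    cell = params.density_cell_m
    nx = max(1, int(round(width_m / cell)))
    ny = max(1, int(round(length_m / cell)))
    if out is not None and out.shape == (ny, nx):
        field = out
        field[:] = 0.0
    else:
        field = np.zeros((ny, nx), dtype=np.float32)
    if len(x_m):
        _deposit(
            field,
            np.ascontiguousarray(x_m, dtype=np.float64),
            np.ascontiguousarray(y_m, dtype=np.float64),
            np.ascontiguousarray(basal_cm, dtype=np.float64),
            np.ascontiguousarray(influence_radius(height_m, params), dtype=np.float64),
            cell,
        )
    return field


def update_environment(
    x_m, y_m, basal_cm, height_m, ndd0_nodes, params: LifeCycleParams,
    width_m: float, length_m: float, out: np.ndarray | None = None,
) -> EnvironmentState:
    """Rebuild the density field from all live trees and estimate the
    active-layer depth per node from a Stefan-type simplification,
    ``edaphic_factor · sqrt(NDD0)``."""
    fld = density_field(x_m, y_m, basal_cm, height_m, params, width_m, length_m, out=out)
    ald = params.edaphic_factor * np.sqrt(np.clip(np.asarray(ndd0_nodes, dtype=float), 0.0, None))
    return EnvironmentState(fld, params.density_cell_m, ald, params.edaphic_factor)


# ---------------------------------------------------------------------------
# node-climate interpolation
# ---------------------------------------------------------------------------


def interpolate_node_climate(y_m, node_km, values, warn_outside: bool = False):
    """Linear interpolation of per-node values at along-transect positions.

    Positions outside the node span clamp to the nearest node.
    """
    node_m = np.asarray(node_km, dtype=float) * 1000.0
    y = np.asarray(y_m, dtype=float)
    if warn_outside and (np.any(y < node_m[0]) or np.any(y > node_m[-1])):
        import warnings

        warnings.warn("positions outside the climate-node span; clamping", stacklevel=2)
    return np.interp(y, node_m, np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# dispersal, production, establishment, mortality
# ---------------------------------------------------------------------------


def disperse_seeds(
    parent_x,
    parent_y,
    release_height_m,
    counts,
    wind_speed,
    wind_direction_deg,
    params: LifeCycleParams,
    width_m: float,
    rng: np.random.Generator,
):
    """Ballistic seed flight from parent trees under sampled winds.

    Per seed, a wind sample (speed, transport bearing) is drawn and the
    horizontal flight distance is ``release_height · speed / fall_velocity``
    — the ballistic model whose distance distribution inherits the wind
    speed's decreasing tail.  x wraps across the east–west margins; y never
    wraps (seeds crossing the north/south ends are returned as-is and are
    discarded by the caller if outside the transect).

    Returns (x, y) arrays of seed positions.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0), np.empty(0)
    px = np.repeat(np.asarray(parent_x, dtype=float), counts)
    py = np.repeat(np.asarray(parent_y, dtype=float), counts)
    ph = np.repeat(np.asarray(release_height_m, dtype=float), counts)
    idx = rng.integers(0, len(wind_speed), size=total)
    dist = ph * np.asarray(wind_speed)[idx] / params.fall_velocity_ms
    theta = np.radians(np.asarray(wind_direction_deg)[idx])
    x = np.mod(px + dist * np.sin(theta), width_m)
    y = py + dist * np.cos(theta)
    return x, y


def produce_seeds(
    height_m,
    maturation_height_m,
    basal_cm,
    density_index,
    weather_factor,
    params: LifeCycleParams,
    rng: np.random.Generator,
):
    """Yearly cone-seed counts per tree (0 below the maturation height).

    Expected count increases with tree size, decreases with competition,
    and scales with a weather factor in [0, 1]; realised counts are
    Poisson.
    """
    h = np.asarray(height_m, dtype=float)
    mature = h >= np.asarray(maturation_height_m, dtype=float)
    size_f = np.asarray(basal_cm, dtype=float) / (
        np.asarray(basal_cm, dtype=float) + params.fecundity_d_half_cm
    )
    lam = (
        params.fecundity_max
        * size_f
        * np.asarray(weather_factor, dtype=float)
        / (1.0 + params.comp_fecundity * np.asarray(density_index, dtype=float))
    )
    lam = np.where(mature, np.clip(lam, 0.0, None), 0.0)
    return rng.poisson(lam)


def establishment_probability(t_jul, density_index, ald_cm, params: LifeCycleParams):
    """Per-seed yearly germination probability in [0, 1]."""
    p = (
        params.germination_p0
        * _logistic((np.asarray(t_jul, dtype=float) - params.t_est_half) / params.t_est_scale)
        * np.exp(-params.comp_establish * np.asarray(density_index, dtype=float))
    )
    return np.where(np.asarray(ald_cm, dtype=float) >= params.ald_min_cm, p, 0.0)


def tree_death_probability(
    basal_cm, age, density_index, t_jul_10yr, drought_10yr, params: LifeCycleParams
):
    """Yearly death probability, 1 − product of survival factors, floored at
    the background rate.

    Hazards: cold July deficit (fading with size — established trees endure
    unfavourable spells), drought (precipitation over degree days below a
    threshold), local density (shading, strongest for small trees), age
    senescence and a juvenile size hazard.
    """
    d = np.asarray(basal_cm, dtype=float)
    a = np.asarray(age, dtype=float)
    di = np.asarray(density_index, dtype=float)
    tj = np.asarray(t_jul_10yr, dtype=float)
    dr = np.asarray(drought_10yr, dtype=float)

    h_cold = (
        params.cold_mort_coef
        * np.clip(params.t_mort_ref - tj, 0.0, None)
        * np.exp(-d / params.cold_juvenile_scale_cm)
    )
    h_drought = params.drought_mort_coef * np.clip(
        (params.drought_index_min - dr) / params.drought_index_min, 0.0, None
    )
    h_dens = params.dens_mort_coef * di * np.exp(-d / params.dens_juvenile_scale_cm)
    h_age = params.age_mort_coef * (a / params.age_max) ** params.age_mort_power
    h_size = params.juvenile_mort * np.exp(-d / params.juvenile_size_scale_cm)
    p = 1.0 - np.exp(-(h_cold + h_drought + h_dens + h_age + h_size))
    return np.clip(p, params.background_mortality, 1.0)


# ---------------------------------------------------------------------------
# simulation state and driver
# ---------------------------------------------------------------------------


@dataclass
class StandSnapshot:
    """All stems (height > 1.3 m) at one output year."""

    year: int
    x_m: np.ndarray
    y_m: np.ndarray
    age: np.ndarray
    basal_cm: np.ndarray
    dbh_cm: np.ndarray
    height_m: np.ndarray

    def to_frame(self, repeat: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": repeat,
                "year": self.year,
                "x_m": self.x_m,
                "y_m": self.y_m,
                "age": self.age,
                "basal_cm": self.basal_cm,
                "dbh_cm": self.dbh_cm,
                "height_m": self.height_m,
            }
        )


@dataclass
class SimulationResult:
    snapshots: list[StandSnapshot]
    log: pd.DataFrame
    config: SimulationConfig
    params: LifeCycleParams
    repeat: int
    rng_seed: int

    def snapshots_frame(self) -> pd.DataFrame:
        if not self.snapshots:
            return pd.DataFrame(
                columns=["repeat", "year", "x_m", "y_m", "age", "basal_cm", "dbh_cm", "height_m"]
            )
        return pd.concat([s.to_frame(self.repeat) for s in self.snapshots], ignore_index=True)


_STREAMS = ("dispersal", "production", "establishment", "mortality", "boundary", "maturation")


class TreelineSimulator:
    """Stateful yearly driver over a forcing window.

    Parameters
    ----------
    config, params : simulation and life-cycle configuration.
    forcing : MonthlyClimateSeries covering the simulated calendar years.
    wind : DataFrame with ``speed_ms`` and ``direction_deg`` columns; if
        None a synthetic record is generated from the boundary stream.
    repeat : repeat number; combined with ``config.rng_seed`` to derive all
        process-local RNG streams.
    """

    def __init__(
        self,
        config: SimulationConfig,
        params: LifeCycleParams,
        forcing: MonthlyClimateSeries,
        wind: pd.DataFrame | None = None,
        repeat: int = 0,
    ):
        self.config = config
        self.params = params
        self.forcing = forcing
        self.repeat = repeat
        self.length_m = config.transect_length_km * 1000.0
        self.width_m = config.transect_width_m
        self.node_km = forcing.node_km
        self._node_m = self.node_km * 1000.0

        # process-local RNG streams derived from fixed labels
        self.rng = {
            name: np.random.default_rng([config.rng_seed, repeat, i])
            for i, name in enumerate(_STREAMS)
        }

        if wind is None:
            from .wind import synth_wind

            wind = synth_wind(20_000, rng_seed=int(np.random.default_rng([config.rng_seed, 97]).integers(2**31)))
        self._wind_speed = wind["speed_ms"].to_numpy(dtype=float)
        self._wind_dir = wind["direction_deg"].to_numpy(dtype=float)

        # per-(node, year) auxiliaries and their trailing 10-yr means
        aux = auxiliary_table(forcing)
        self.aux = aux
        self.aux10 = {k: _trailing_mean(v, 10) for k, v in aux.items()}

        # state
        self.tx = np.empty(0)
        self.ty = np.empty(0)
        self.t_age = np.empty(0, dtype=np.int64)
        self.t_basal = np.empty(0)
        self.t_mat_h = np.empty(0)
        self.t_cones = np.empty(0, dtype=np.int64)
        self.t_di = np.empty(0)
        self.sx = np.empty(0)
        self.sy = np.empty(0)
        self.s_age = np.empty(0, dtype=np.int64)
        self.env: EnvironmentState | None = None
        self._log_rows: list[tuple] = []
        self._snapshots: list[StandSnapshot] = []

    # -- helpers -----------------------------------------------------------

    @property
    def t_height(self) -> np.ndarray:
        return tree_height(self.t_basal, self.params)

    def _interp(self, table: dict, key: str, year_idx: int, y_m: np.ndarray) -> np.ndarray:
        return interpolate_node_climate(y_m, self.node_km, table[key][:, year_idx])

    def _add_trees(self, x, y, basal=None):
        n = len(x)
        if n == 0:
            return
        p = self.params
        self.tx = np.concatenate([self.tx, x])
        self.ty = np.concatenate([self.ty, y])
        self.t_age = np.concatenate([self.t_age, np.zeros(n, dtype=np.int64)])
        self.t_basal = np.concatenate(
            [self.t_basal, np.full(n, p.seedling_basal_cm) if basal is None else basal]
        )
        mat = np.clip(
            self.rng["maturation"].normal(p.maturation_height_mean_m, p.maturation_height_sd_m, n),
            p.maturation_height_min_m,
            None,
        )
        self.t_mat_h = np.concatenate([self.t_mat_h, mat])
        self.t_cones = np.concatenate([self.t_cones, np.zeros(n, dtype=np.int64)])
        self.t_di = np.concatenate([self.t_di, np.zeros(n)])

    def _add_seeds(self, x, y):
        keep = (y >= 0.0) & (y <= self.length_m)
        x, y = x[keep], y[keep]
        self.sx = np.concatenate([self.sx, np.mod(x, self.width_m)])
        self.sy = np.concatenate([self.sy, y])
        self.s_age = np.concatenate([self.s_age, np.zeros(len(x), dtype=np.int64)])

    def _filter_trees(self, keep: np.ndarray):
        self.tx, self.ty = self.tx[keep], self.ty[keep]
        self.t_age, self.t_basal = self.t_age[keep], self.t_basal[keep]
        self.t_mat_h, self.t_cones = self.t_mat_h[keep], self.t_cones[keep]
        self.t_di = self.t_di[keep]

    # -- yearly processes ---------------------------------------------------

    def introduce_boundary_seeds(self, stab_year: int | None, year_idx: int) -> None:
        """Initial pulse (stabilization years 1–50), permanent background
        rain proportional to transect length, and climate-scaled hinterland
        seed rain on the first 500 m."""
        cfg, p = self.config, self.params
        rng = self.rng["boundary"]
        if not cfg.enable_boundary_seeds:
            return
        length_km = cfg.transect_length_km
        # initial pulse from the forested (southern) boundary
        if stab_year is not None and stab_year < cfg.initial_seed_years:
            y = rng.exponential(cfg.initial_seed_mean_m, size=cfg.initial_seed_count)
            x = rng.uniform(0.0, self.width_m, size=cfg.initial_seed_count)
            self._add_seeds(x, y)  # _add_seeds drops positions beyond the transect
        # permanent background seeds, uniform along the transect
        n_bg = background_seed_count(cfg)
        if n_bg:
            self._add_seeds(
                rng.uniform(0.0, self.width_m, size=n_bg),
                rng.uniform(0.0, self.length_m, size=n_bg),
            )
        # hinterland stretch: climate-scaled rain, release height tied to
        # the climate-predicted tree height at the boundary
        if cfg.hinterland_rate > 0:
            t_jul10 = float(self.aux10["t_jul"][0, year_idx])
            weather = float(
                _logistic((t_jul10 - p.t_jul_half) / p.t_jul_scale) * (t_jul10 >= p.t_jul_cold)
            )
            n_h = int(rng.poisson(cfg.hinterland_rate * weather))
            if n_h:
                h_star = p.height_max_m * weather
                y0 = rng.uniform(0.0, cfg.hinterland_stretch_m, size=n_h)
                x0 = rng.uniform(0.0, self.width_m, size=n_h)
                idx = rng.integers(0, len(self._wind_speed), size=n_h)
                dist = h_star * self._wind_speed[idx] / p.fall_velocity_ms
                theta = np.radians(self._wind_dir[idx])
                self._add_seeds(x0 + dist * np.sin(theta), y0 + dist * np.cos(theta))

    def run_year(self, year_idx: int, stab_year: int | None = None) -> None:
        """One yearly cycle at forcing-year index ``year_idx``."""
        cfg, p = self.config, self.params

        # 1. environment (field buffer reused across years)
        if not hasattr(self, "_field_buf"):
            cell = p.density_cell_m
            self._field_buf = np.zeros(
                (max(1, int(round(self.length_m / cell))), max(1, int(round(self.width_m / cell)))),
                dtype=np.float32,
            )
        self.env = update_environment(
            self.tx, self.ty, self.t_basal, self.t_height,
            self.aux["ndd0"][:, year_idx], p, self.width_m, self.length_m,
            out=self._field_buf,
        )
        if len(self.tx):
            raw = self.env.sample(self.tx, self.ty)
            # subtract each tree's own central deposit
            cell = self.env.cell_m
            cx = (np.floor(self.tx / cell) + 0.5) * cell
            cy = (np.floor(self.ty / cell) + 0.5) * cell
            d_self = np.hypot(self.tx - cx, self.ty - cy)
            w_self = np.clip(1.0 - d_self / influence_radius(self.t_height, p), 0.0, None)
            self.t_di = np.clip(raw - self.t_basal * w_self, 0.0, None)

        # 2. growth (10-yr mean climate, reduced by competition)
        if len(self.tx):
            t_jul10 = self._interp(self.aux10, "t_jul", year_idx, self.ty)
            ndd10 = self._interp(self.aux10, "ndd0", year_idx, self.ty)
            self.t_basal = grow_trees(
                self.t_basal, compute_max_growth(t_jul10, ndd10, p), self.t_di, p
            )

        # 3. dispersal of last year's cones
        if cfg.enable_dispersal and len(self.tx) and self.t_cones.sum():
            x, y = disperse_seeds(
                self.tx, self.ty, self.t_height, self.t_cones,
                self._wind_speed, self._wind_dir, p, self.width_m, self.rng["dispersal"],
            )
            self._add_seeds(x, y)
        self.t_cones[:] = 0

        # 4. seed production (held in cones until next year's dispersal)
        if len(self.tx):
            t_jul_now = self._interp(self.aux, "t_jul", year_idx, self.ty)
            weather = _logistic((t_jul_now - p.t_jul_half) / p.t_jul_scale)
            weather = np.where(t_jul_now < p.t_jul_cold, 0.0, weather)
            self.t_cones = produce_seeds(
                self.t_height, self.t_mat_h, self.t_basal, self.t_di,
                weather, p, self.rng["production"],
            )

        # boundary / hinterland seed input
        self.introduce_boundary_seeds(stab_year, year_idx)

        # 5. establishment of ground seeds
        if cfg.enable_establishment and len(self.sx):
            t_jul_s = self._interp(self.aux, "t_jul", year_idx, self.sy)
            ald_s = interpolate_node_climate(self.sy, self.node_km, self.env.active_layer_depth)
            di_s = self.env.sample(self.sx, self.sy)
            p_est = establishment_probability(t_jul_s, di_s, ald_s, p)
            germ = self.rng["establishment"].random(len(self.sx)) < p_est
            if germ.any():
                self._add_trees(self.sx[germ], self.sy[germ])
            keep = ~germ
            self.sx, self.sy, self.s_age = self.sx[keep], self.sy[keep], self.s_age[keep]

        # 6. mortality
        if cfg.enable_mortality:
            if len(self.tx):
                t_jul10 = self._interp(self.aux10, "t_jul", year_idx, self.ty)
                dr10 = self._interp(self.aux10, "drought_index", year_idx, self.ty)
                p_die = tree_death_probability(
                    self.t_basal, self.t_age, self.t_di, t_jul10, dr10, p
                )
                self._filter_trees(self.rng["mortality"].random(len(self.tx)) >= p_die)
            if len(self.sx):
                keep = self.rng["mortality"].random(len(self.sx)) >= p.seed_mortality
                self.sx, self.sy, self.s_age = self.sx[keep], self.sy[keep], self.s_age[keep]
            if len(self.tx) and self.t_cones.sum():
                self.t_cones = self.rng["mortality"].binomial(
                    self.t_cones, 1.0 - p.seed_mortality
                )

        # 7. ageing; over-age seeds leave the system
        self.t_age = self.t_age + 1
        self.s_age = self.s_age + 1
        keep = self.s_age <= p.seed_age_limit
        self.sx, self.sy, self.s_age = self.sx[keep], self.sy[keep], self.s_age[keep]

    # -- driver -------------------------------------------------------------

    def run(self) -> SimulationResult:
        """Stabilization (looped early climate) followed by the forcing years,
        with decadal stem snapshots and a yearly structured log."""
        cfg = self.config
        years = self.forcing.years
        loop = min(cfg.stabilization_loop_years, len(years))
        for s in range(cfg.stabilization_years):
            self.run_year(s % loop, stab_year=s)
            self._log(int(years[0]) - cfg.stabilization_years + s, phase="stabilization")
        for i, year in enumerate(years):
            self.run_year(i, stab_year=None)
            self._log(int(year), phase="main")
            if year % cfg.snapshot_interval == 0:
                self._take_snapshot(int(year))
        log = pd.DataFrame(
            self._log_rows,
            columns=["year", "phase", "n_trees", "n_stems", "n_ground_seeds", "northernmost_stem_m"],
        )
        return SimulationResult(
            snapshots=self._snapshots,
            log=log,
            config=cfg,
            params=self.params,
            repeat=self.repeat,
            rng_seed=cfg.rng_seed,
        )

    def _take_snapshot(self, year: int) -> None:
        h = self.t_height
        stems = h > self.params.breast_height_m
        self._snapshots.append(
            StandSnapshot(
                year=year,
                x_m=self.tx[stems].astype(np.float32),
                y_m=self.ty[stems].astype(np.float32),
                age=self.t_age[stems].astype(np.int32),
                basal_cm=self.t_basal[stems].astype(np.float32),
                dbh_cm=breast_height_diameter(self.t_basal[stems], h[stems], self.params).astype(
                    np.float32
                ),
                height_m=h[stems].astype(np.float32),
            )
        )

    def _log(self, year: int, phase: str) -> None:
        h = self.t_height
        stems = h > self.params.breast_height_m
        north = float(self.ty[stems].max()) if stems.any() else np.nan
        self._log_rows.append(
            (year, phase, len(self.tx), int(stems.sum()), len(self.sx), north)
        )


def background_seed_count(config: SimulationConfig) -> int:
    """Permanent yearly boundary seeds: 1000 per 200 km of transect length."""
    return int(round(config.permanent_seeds_per_200km * config.transect_length_km / 200.0))


def _trailing_mean(arr: np.ndarray, window: int) -> np.ndarray:
    """Trailing mean over the year axis (axis 1), shrinking at the start."""
    c = np.cumsum(arr, axis=1)
    out = np.empty_like(arr, dtype=float)
    n_years = arr.shape[1]
    for i in range(n_years):
        lo = max(0, i - window + 1)
        total = c[:, i] - (c[:, lo - 1] if lo > 0 else 0.0)
        out[:, i] = total / (i - lo + 1)
    return out


def run_simulation(
    config: SimulationConfig,
    forcing: MonthlyClimateSeries,
    params: LifeCycleParams | None = None,
    wind: pd.DataFrame | None = None,
    repeat: int = 0,
) -> SimulationResult:
    """Run one repeat of the life-cycle simulation over a forcing window.

    Raises if the forcing has any year gap (validated on construction) or
    is empty.
    """
    if params is None:
        params = LifeCycleParams()
    if forcing.n_years == 0:
        raise ValueError("forcing covers no years")
    sim = TreelineSimulator(config, params, forcing, wind=wind, repeat=repeat)
    return sim.run()
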