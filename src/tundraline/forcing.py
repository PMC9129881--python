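"""Millennium-scale climate forcing construction for treeline transects.

A transect forcing covering 501–3000 CE is assembled in six steps:

1. obtain (or synthesise) an instrumental-era monthly series per 10-km node;
2. extend an annual ice-core-like proxy back to 501 CE by resampling
   25-year blocks of its pre-industrial (<1800 CE) portion;
3. calibrate the proxy against instrumental annual means over 1901–1998 by
   per-node ordinary least squares, and reconstruct per-node annual mean
   temperature / annual precipitation for 501–1900;
4. assemble monthly pre-instrumental series by resampling 15-year blocks of
   instrumental months, shifting each year so its annual mean matches the
   reconstruction (additive for temperature, multiplicative for
   precipitation);
5. append a warming-scenario block to 2300 built from a July-anomaly trend
   curve laid over resampled modern years;
6. extend the 2100–2300 trend to 2500 and then either loop the 1901–1978
   data ("20th-century cooling") or copy 2300–2500 repeatedly ("continued")
   until 3000 CE.

Region-level lapse-rate offsets and the synthetic stand-in generators for
the instrumental series and the proxy live here as well.  Real data can be
dropped in through the same tabular interfaces
(:meth:`~tundraline.climate.MonthlyClimateSeries.from_frame` and
:class:`AnnualProxySeries`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .climate import MonthlyClimateSeries, NODE_SPACING_KM, concat_years

__all__ = [
    "AnnualProxySeries",
    "ScenarioSpec",
    "RegionOffsets",
    "AnnualMeans",
    "ProxyCalibration",
    "SCENARIO_IDS",
    "JULY_MEDIAN_2100",
    "JULY_ANOMALY_2300",
    "DEFAULT_REGION_OFFSETS",
    "extend_proxy_series",
    "calibrate_to_instrumental",
    "assemble_monthly_preinstrumental",
    "synth_scenario_curve",
    "append_scenario",
    "apply_region_offsets",
    "synth_instrumental",
    "synth_proxy",
    "build_forcing",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AnnualProxySeries:
    """Annual-resolution proxy series (δ18O-like value + layer thickness)."""

    years: np.ndarray
    value: np.ndarray
    thickness: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        self.thickness = np.asarray(self.thickness, dtype=float)
        if len(self.years) > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("proxy years must be contiguous and increasing")
        if not (len(self.years) == len(self.value) == len(self.thickness)):
            raise ValueError("proxy arrays must have equal length")

    def window(self, start: int, stop: int) -> "AnnualProxySeries":
        m = (self.years >= start) & (self.years <= stop)
        return AnnualProxySeries(self.years[m], self.value[m], self.thickness[m])


SCENARIO_IDS = ("RCP2.6*", "RCP2.6", "RCP4.5", "RCP8.5")

# Median July warming by 2100 relative to 1970–2000 (°C), per scenario.
JULY_MEDIAN_2100 = {"RCP2.6*": 1.2, "RCP2.6": 1.8, "RCP4.5": 2.1, "RCP8.5": 5.0}

# July anomaly level reached by 2300 (°C).  RCP2.6* carries no independent
# 2300 level: its whole curve is constructed as half the RCP2.6 anomaly.
JULY_ANOMALY_2300 = {"RCP2.6": 0.5, "RCP4.5": 3.1, "RCP8.5": 14.4}


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: str
    post_peak_mode: str = "continued"  # "cooling" | "continued"
    july_warming_median_2100: float | None = None

    def __post_init__(self):
        if self.scenario_id not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario_id {self.scenario_id!r}")
        if self.post_peak_mode not in ("cooling", "continued"):
            raise ValueError(f"unknown post_peak_mode {self.post_peak_mode!r}")
        if self.july_warming_median_2100 is None:
            object.__setattr__(
                self, "july_warming_median_2100", JULY_MEDIAN_2100[self.scenario_id]
            )


# Tuned regional lapse-rate amendments (°C for Jan/Jul, mm for annual precip).
DEFAULT_REGION_OFFSETS = {
    "Taimyr": (-1.17, -0.84, -5.4),
    "BuorKhaya": (-0.23, -2.48, -28.9),
    "Kolyma": (+3.14, +1.26, +85.7),
    "Chukotka": (+4.46, +4.30, +8.2),
}


@dataclass(frozen=True)
class RegionOffsets:
    region_name: str
    d_t_jan: float = 0.0
    d_t_jul: float = 0.0
    d_p_year: float = 0.0

    @classmethod
    def for_region(cls, region_name: str) -> "RegionOffsets":
        jan, jul, p = DEFAULT_REGION_OFFSETS[region_name]
        return cls(region_name, jan, jul, p)


# ---------------------------------------------------------------------------
# step 2: proxy extension by pre-industrial block resampling
# ---------------------------------------------------------------------------


def extend_proxy_series(
    reference: AnnualProxySeries,
    block_len: int = 25,
    preindustrial_cutoff: int = 1800,
    rng_seed: int = 0,
    target_span: tuple[int, int] = (501, 1900),
) -> AnnualProxySeries:
    """Extend a reference proxy over ``target_span`` from pre-industrial blocks.

    Contiguous ``block_len``-year blocks whose years all precede
    ``preindustrial_cutoff`` are sampled (with replacement, uniformly over
    admissible start years) and stitched end-to-end; the final block is
    truncated to fit.  Joins are not smoothed.
    """
    pre = reference.years < preindustrial_cutoff
    n_pre = int(pre.sum())
    if n_pre < block_len:
        raise ValueError(
            f"reference has only {n_pre} pre-{preindustrial_cutoff} years; "
            f"need at least block_len={block_len}"
        )
    # admissible block starts: indices whose whole block lies pre-cutoff
    last_pre = int(np.nonzero(pre)[0][-1])
    starts = np.arange(0, last_pre - block_len + 2)
    rng = np.random.default_rng(rng_seed)

    y0, y1 = target_span
    n_target = y1 - y0 + 1
    value = np.empty(n_target)
    thickness = np.empty(n_target)
    pos = 0
    while pos < n_target:
        s = int(rng.choice(starts))
        n = min(block_len, n_target - pos)
        value[pos : pos + n] = reference.value[s : s + n]
        thickness[pos : pos + n] = reference.thickness[s : s + n]
        pos += n
    return AnnualProxySeries(np.arange(y0, y1 + 1), value, thickness)


# ---------------------------------------------------------------------------
# step 3: proxy → annual means by per-node OLS over the instrumental overlap
# ---------------------------------------------------------------------------


@dataclass
class AnnualMeans:
    """Per-node annual mean temperature and annual precipitation estimates."""

    node_km: np.ndarray
    years: np.ndarray
    temp_mean: np.ndarray  # (n_nodes, n_years), °C
    precip_total: np.ndarray  # (n_nodes, n_years), mm


@dataclass
class ProxyCalibration:
    node_km: np.ndarray
    temp_slope: np.ndarray
    temp_intercept: np.ndarray
    precip_slope: np.ndarray
    precip_intercept: np.ndarray

    def predict(self, proxy: AnnualProxySeries) -> AnnualMeans:
        v = proxy.value[None, :]
        return AnnualMeans(
            node_km=self.node_km.copy(),
            years=proxy.years.copy(),
            temp_mean=self.temp_intercept[:, None] + self.temp_slope[:, None] * v,
            precip_total=np.clip(
                self.precip_intercept[:, None] + self.precip_slope[:, None] * v,
                0.0,
                None,
            ),
        )


def calibrate_to_instrumental(
    proxy: AnnualProxySeries,
    instrumental: MonthlyClimateSeries,
    overlap: tuple[int, int] = (1901, 1998),
) -> ProxyCalibration:
    """Per-node OLS of annual mean temperature / precipitation on proxy value.

    Raises
    ------
    ValueError
        If the proxy has zero variance over the overlap (a degenerate fit
        cannot be silently accepted).
    """
    o0, o1 = overlap
    pm = (proxy.years >= o0) & (proxy.years <= o1)
    if pm.sum() == 0:
        raise ValueError("overlap years missing from proxy")
    x = proxy.value[pm]
    if np.var(x) == 0.0:
        raise ValueError("proxy has zero variance over the overlap: degenerate fit")
    inst = instrumental.slice_years(o0, o1)
    if len(inst.years) != len(x):
        raise ValueError("overlap years missing from instrumental series")

    t_ann = inst.annual_mean_temp()
    p_ann = inst.annual_precip()
    n = instrumental.n_nodes
    ts, ti, ps, pi = (np.empty(n) for _ in range(4))
    for i in range(n):
        rt = stats.linregress(x, t_ann[i])
        rp = stats.linregress(x, p_ann[i])
        ts[i], ti[i] = rt.slope, rt.intercept
        ps[i], pi[i] = rp.slope, rp.intercept
    return ProxyCalibration(
        node_km=instrumental.node_km.copy(),
        temp_slope=ts,
        temp_intercept=ti,
        precip_slope=ps,
        precip_intercept=pi,
    )


# ---------------------------------------------------------------------------
# step 4: monthly assembly from resampled instrumental blocks
# ---------------------------------------------------------------------------


def assemble_monthly_preinstrumental(
    annual_means: AnnualMeans,
    instrumental: MonthlyClimateSeries,
    block_len: int = 15,
    rng_seed: int = 0,
) -> MonthlyClimateSeries:
    """Build a monthly series matching reconstructed annual means.

    For every ``block_len``-year window of the target span a source block of
    instrumental years is drawn (the same source years at all nodes, which
    preserves the spatial coherence of weather); each target year's months
    are then the source year's months shifted additively (temperature) or
    rescaled multiplicatively (precipitation) so that the annual mean /
    total reproduces ``annual_means`` exactly.
    """
    if not np.allclose(annual_means.node_km, instrumental.node_km):
        raise ValueError("annual_means and instrumental nodes differ")
    rng = np.random.default_rng(rng_seed)
    n_src = instrumental.n_years
    if n_src < block_len:
        raise ValueError("instrumental series shorter than block_len")

    years = annual_means.years
    n_target = len(years)
    src_idx = np.empty(n_target, dtype=int)
    pos = 0
    while pos < n_target:
        s = int(rng.integers(0, n_src - block_len + 1))
        n = min(block_len, n_target - pos)
        src_idx[pos : pos + n] = np.arange(s, s + n)
        pos += n

    t_src = instrumental.temp[:, src_idx, :]  # (nodes, target, 12)
    p_src = instrumental.precip[:, src_idx, :]
    t_shift = annual_means.temp_mean - t_src.mean(axis=2)
    temp = t_src + t_shift[:, :, None]
    src_tot = p_src.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(src_tot > 0, annual_means.precip_total / np.maximum(src_tot, 1e-12), 0.0)
    precip = p_src * scale[:, :, None]
    # a dry source year cannot be rescaled: spread the target total evenly
    dry = src_tot <= 0
    if dry.any():
        precip[dry] = (annual_means.precip_total[dry] / 12.0)[:, None]
    return MonthlyClimateSeries(
        node_km=instrumental.node_km.copy(), years=years.copy(), temp=temp, precip=precip
    )


# ---------------------------------------------------------------------------
# steps 5–6: scenario curves and appending to 3000 CE
# ---------------------------------------------------------------------------


def synth_scenario_curve(
    scenario_id: str,
    years: tuple[int, int] = (2006, 2300),
    peak_year: int = 2100,
) -> dict[str, np.ndarray]:
    """July-anomaly trend curve (°C vs the 1970–2000 baseline) to 2300.

    The ramp to the 2100 peak is logistic in time (midpoint 2060, scale
    18 yr) normalised so the 2100 value equals the scenario's median July
    warming; from 2100 the curve moves linearly to its 2300 level.
    RCP2.6* is, by construction, half the RCP2.6 anomaly at every year.
    """
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario_id {scenario_id!r}")
    if scenario_id == "RCP2.6*":
        base = synth_scenario_curve("RCP2.6", years=years, peak_year=peak_year)
        return {"year": base["year"], "anomaly": 0.5 * base["anomaly"]}
    y0, y1 = years
    yr = np.arange(y0, y1 + 1)
    peak = JULY_MEDIAN_2100[scenario_id]
    level_2300 = JULY_ANOMALY_2300[scenario_id]

    def logistic(t):
        return 1.0 / (1.0 + np.exp(-(t - 2060.0) / 18.0))

    ramp = (logistic(yr) - logistic(y0)) / (logistic(peak_year) - logistic(y0))
    anomaly = peak * ramp
    post = yr > peak_year
    anomaly[post] = peak + (level_2300 - peak) * (yr[post] - peak_year) / (2300 - peak_year)
    return {"year": yr, "anomaly": anomaly}


# precipitation responds to warming at the Clausius–Clapeyron rate of
# ~7 %/°C in the synthetic scenarios
_PRECIP_PER_DEGC = 0.07


def append_scenario(
    series: MonthlyClimateSeries,
    spec: ScenarioSpec,
    scenario_curve: dict[str, np.ndarray] | None = None,
    rng_seed: int = 0,
) -> MonthlyClimateSeries:
    """Append scenario years so the series covers through 3000 CE.

    2006–2300 lays the anomaly curve over modern years resampled from the
    last 30 instrumental years; 2301–2500 continues the per-(node, month)
    linear trend fitted to 2100–2300, recycling detrended residual years;
    2501–3000 either loops the 1901–1978 data ("cooling") or copies the
    2300–2500 block repeatedly ("continued").

    In cooling mode the final, partial 78-year cycle is bias-corrected
    (additively for temperature, multiplicatively for precipitation) so the
    2501–3000 mean state equals the 1901–1978 mean state exactly per node
    and month.
    """
    if series.years[-1] < 2000:
        raise ValueError("input series must extend to at least year 2000")
    if scenario_curve is None:
        scenario_curve = synth_scenario_curve(spec.scenario_id)
    cy, ca = np.asarray(scenario_curve["year"]), np.asarray(scenario_curve["anomaly"])
    if cy[0] > 2006 or cy[-1] < 2300:
        raise ValueError("scenario curve must cover 2006–2300")

    rng = np.random.default_rng(rng_seed)
    base = series.slice_years(series.years[-1] - 29, series.years[-1])  # modern 30 yr

    # --- 2006(or next)–2300: anomaly over resampled modern years ----------
    start = int(series.years[-1]) + 1
    yrs_a = np.arange(start, 2301)
    pick = rng.integers(0, base.n_years, size=len(yrs_a))
    anom = np.interp(yrs_a, cy, ca)
    temp_a = base.temp[:, pick, :] + anom[None, :, None]
    precip_a = base.precip[:, pick, :] * (1.0 + _PRECIP_PER_DEGC * anom[None, :, None])
    part_a = MonthlyClimateSeries(series.node_km, yrs_a, temp_a, np.clip(precip_a, 0, None))
    full = concat_years(series, part_a)

    # --- 2301–2500: extend the 2100–2300 linear trend ----------------------
    fit = full.slice_years(2100, 2300)
    fy = fit.years.astype(float)
    fym = fy.mean()
    X = fy - fym
    denom = (X**2).sum()

    def trend_extend(arr):  # arr: (nodes, 201, 12)
        mean = arr.mean(axis=1, keepdims=True)
        slope = np.einsum("y,nym->nm", X, arr - mean) / denom  # (nodes, 12)
        resid = arr - mean - slope[:, None, :] * X[None, :, None]
        yrs_b = np.arange(2301, 2501)
        src = (yrs_b - 2301) % 200 + 1  # recycle residual years 2101..2300
        pred = mean[:, 0, :][:, None, :] + slope[:, None, :] * (yrs_b - fym)[None, :, None]
        return pred + resid[:, src, :]

    part_b = MonthlyClimateSeries(
        series.node_km,
        np.arange(2301, 2501),
        trend_extend(fit.temp),
        np.clip(trend_extend(fit.precip), 0, None),
    )
    full = concat_years(full, part_b)

    # --- 2501–3000: cooling loop or continued copy -------------------------
    yrs_c = np.arange(2501, 3001)
    if spec.post_peak_mode == "continued":
        src_years = 2301 + (yrs_c - 2501) % 200
        i0 = full.year_index(2301)
        idx = i0 + (src_years - 2301)
        temp_c = full.temp[:, idx, :]
        precip_c = full.precip[:, idx, :]
    else:  # cooling: loop 1901–1978
        loop = full.slice_years(1901, 1978)
        idx = (yrs_c - 2501) % 78
        temp_c = loop.temp[:, idx, :].copy()
        precip_c = loop.precip[:, idx, :].copy()
        # bias-correct so the 2501–3000 mean state equals 1901–1978 exactly
        # (the loop length does not divide 500, so the raw tiling is biased
        # by the partial final cycle; a uniform per-(node, month) shift —
        # additive for temperature, multiplicative for precipitation —
        # restores the 20th-century mean state by construction)
        if len(yrs_c) % 78 != 0:
            t_target = loop.temp.mean(axis=1)  # (nodes, 12)
            temp_c += (t_target - temp_c.mean(axis=1))[:, None, :]
            p_target = loop.precip.mean(axis=1)
            p_all = precip_c.mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = np.where(p_all > 0, p_target / np.maximum(p_all, 1e-12), 1.0)
            precip_c *= corr[:, None, :]
    part_c = MonthlyClimateSeries(series.node_km, yrs_c, temp_c, np.clip(precip_c, 0, None))
    return concat_years(full, part_c)


# ---------------------------------------------------------------------------
# regional lapse-rate offsets
# ---------------------------------------------------------------------------


def apply_region_offsets(
    series: MonthlyClimateSeries, offsets: RegionOffsets
) -> MonthlyClimateSeries:
    """Apply tuned regional lapse-rate amendments.

    January temperature shifts by ``d_t_jan`` and July by ``d_t_jul``;
    other months interpolate between the two with a cosine weight over the
    annual cycle.  Annual precipitation is rescaled multiplicatively so the
    annual total changes by ``d_p_year``; a target total below zero clamps
    every month to zero (with a warning).
    """
    months = np.arange(1, 13)
    w_jan = 0.5 * (1.0 + np.cos(2.0 * np.pi * (months - 1) / 12.0))  # 1 in Jan, 0 in Jul
    dt = offsets.d_t_jan * w_jan + offsets.d_t_jul * (1.0 - w_jan)
    temp = series.temp + dt[None, None, :]

    totals = series.annual_precip()  # (nodes, years)
    target = totals + offsets.d_p_year
    if np.any(target < 0):
        warnings.warn(
            "precipitation offset drives some annual totals negative; clamping to 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(totals > 0, np.clip(target, 0, None) / np.maximum(totals, 1e-12), 0.0)
    precip = series.precip * scale[:, :, None]
    dry = (totals <= 0) & (target > 0)
    if dry.any():
        precip[dry] = (target[dry] / 12.0)[:, None]
    return MonthlyClimateSeries(series.node_km.copy(), series.years.copy(), temp, precip)


# ---------------------------------------------------------------------------
# synthetic stand-in generators
# ---------------------------------------------------------------------------

# Siberian treeline monthly climatology anchored so July equals base_t_jul.
_CLIM_T = np.array([-33.0, -31.0, -24.0, -14.0, -4.0, 6.0, 12.0, 9.0, 3.0, -8.0, -23.0, -30.0])
_CLIM_P = np.array([12.0, 10.0, 10.0, 11.0, 13.0, 26.0, 33.0, 35.0, 25.0, 20.0, 14.0, 12.0])


def synth_instrumental(
    n_nodes: int,
    years: tuple[int, int] = (1901, 2005),
    latitudinal_gradient: float = 1.0,
    rng_seed: int = 0,
    base_t_jul: float = 12.0,
    noise_scale: float = 1.0,
    annual_anomaly: np.ndarray | None = None,
) -> MonthlyClimateSeries:
    """Synthetic instrumental-era monthly series (CRU-like stand-in).

    Seasonal climatology plus AR(1) interannual anomaly plus white monthly
    noise; July temperature decreases poleward by ``latitudinal_gradient``
    °C per 100 km of node position.  ``noise_scale`` scales every noise
    term (0 gives an exactly periodic series); ``annual_anomaly`` may
    supply a shared large-scale annual anomaly (°C, one per year) so a
    proxy series can be generated coherently with the instrumental record.
    """
    if latitudinal_gradient <= 0:
        raise ValueError("latitudinal_gradient must be positive (colder poleward)")
    rng = np.random.default_rng(rng_seed)
    y0, y1 = years
    yrs = np.arange(y0, y1 + 1)
    node_km = np.arange(n_nodes) * NODE_SPACING_KM

    clim_t = _CLIM_T + (base_t_jul - _CLIM_T[6])
    if annual_anomaly is None:
        annual_anomaly = _ar1(len(yrs), phi=0.6, sigma=0.6, rng=rng) * noise_scale
    else:
        annual_anomaly = np.asarray(annual_anomaly, dtype=float)
        if len(annual_anomaly) != len(yrs):
            raise ValueError("annual_anomaly length must match the year span")

    grad = latitudinal_gradient * node_km / 100.0  # °C, subtracted at each node
    # monthly weather noise is synoptic-scale: shared across the ≤100-km
    # node span, with only a small node-local residual
    shared = rng.normal(0.0, 1.2, size=(1, len(yrs), 12))
    local = rng.normal(0.0, 0.2, size=(n_nodes, len(yrs), 12))
    temp = (
        clim_t[None, None, :]
        - grad[:, None, None]
        + annual_anomaly[None, :, None]
        + noise_scale * (shared + local)
    )
    # multiplicative gamma weather noise around the precip climatology
    if noise_scale > 0:
        k = 1.0 / (0.5 * noise_scale) ** 2
        pnoise = rng.gamma(shape=k, scale=1.0 / k, size=(1, len(yrs), 12))
    else:
        pnoise = np.ones((1, len(yrs), 12))
    precip = np.broadcast_to(_CLIM_P[None, None, :] * pnoise, (n_nodes, len(yrs), 12)).copy()
    return MonthlyClimateSeries(node_km=node_km, years=yrs, temp=temp, precip=precip)


def _ar1(n: int, phi: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - phi**2))
    eps = rng.normal(0.0, sigma, size=n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x


def synth_proxy(
    years: tuple[int, int] = (934, 1998),
    rng_seed: int = 0,
    annual_anomaly: np.ndarray | None = None,
    anomaly_years: np.ndarray | None = None,
    slope: float = 1.5,
    noise_sd: float = 0.4,
) -> AnnualProxySeries:
    """Synthetic annual ice-core-like proxy (δ18O-like value + thickness).

    When ``annual_anomaly`` (with its ``anomaly_years``) is given, the proxy
    value tracks that shared large-scale anomaly over the overlapping years,
    so that a later instrumental calibration has real signal to recover.
    """
    rng = np.random.default_rng(rng_seed)
    y0, y1 = years
    yrs = np.arange(y0, y1 + 1)
    signal = _ar1(len(yrs), phi=0.6, sigma=0.6, rng=rng)
    if annual_anomaly is not None:
        anomaly_years = np.asarray(anomaly_years, dtype=int)
        m = np.isin(yrs, anomaly_years)
        src = np.isin(anomaly_years, yrs)
        signal[m] = np.asarray(annual_anomaly, dtype=float)[src]
    value = -20.0 + slope * signal + rng.normal(0.0, noise_sd, size=len(yrs))
    thickness = np.exp(rng.normal(0.0, 0.2, size=len(yrs)))
    return AnnualProxySeries(yrs, value, thickness)


# ---------------------------------------------------------------------------
# end-to-end assembly
# ---------------------------------------------------------------------------


def build_forcing(
    spec: ScenarioSpec,
    n_nodes: int = 6,
    latitudinal_gradient: float = 1.0,
    base_t_jul: float = 12.0,
    offsets: RegionOffsets | None = None,
    rng_seed: int = 0,
) -> MonthlyClimateSeries:
    """Run the full six-step construction on synthetic stand-in inputs.

    Returns a per-node monthly series covering 501–3000 CE.
    """
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(5)
    inst = synth_instrumental(
        n_nodes,
        years=(1901, 2005),
        latitudinal_gradient=latitudinal_gradient,
        base_t_jul=base_t_jul,
        rng_seed=int(seeds[0]),
    )
    anomaly = inst.annual_mean_temp().mean(axis=0)
    anomaly = anomaly - anomaly.mean()
    proxy_ref = synth_proxy(
        years=(934, 1998),
        rng_seed=int(seeds[1]),
        annual_anomaly=anomaly[: 1998 - 1901 + 1],
        anomaly_years=inst.years[: 1998 - 1901 + 1],
    )
    extended = extend_proxy_series(proxy_ref, rng_seed=int(seeds[2]))
    calib = calibrate_to_instrumental(proxy_ref, inst)
    means = calib.predict(extended)
    pre = assemble_monthly_preinstrumental(means, inst, rng_seed=int(seeds[3]))
    series = concat_years(pre, inst)
    series = append_scenario(series, spec, rng_seed=int(seeds[4]))
    if offsets is not None:
        series = apply_region_offsets(series, offsets)
    return series
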