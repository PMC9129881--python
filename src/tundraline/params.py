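"""Life-cycle parameterisation and simulation configuration.

The response-surface shapes (growth, allometry, competition, germination,
mortality, fecundity) are explicit parameterised forms with every constant
collected here, loadable from a single YAML config file.  They are chosen
so a *Larix gmelinii*-like species reproduces the qualitative treeline
behaviours — a sharp cold viability edge near the 10 °C July isotherm,
decadal-scale times from germination to the 1.3-m stem threshold, long
adult persistence under cooling, and competition-limited stand densities —
rather than to be bit-compatible with any particular prior implementation.
Units are noted per field; lengths in metres, diameters in cm, ages in
years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

__all__ = ["LifeCycleParams", "SimulationConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class LifeCycleParams:
    # --- potential growth response (basal diameter increment, cm/yr) -----
    g_max_cm: float = 0.06          # increment on the warm plateau (treeline larch
                                    # radial growth is sub-millimetre per year)
    t_jul_cold: float = 9.0         # hard zero below this July temperature (°C)
    t_jul_half: float = 10.5        # logistic midpoint of the July response (°C)
    t_jul_scale: float = 0.7        # logistic scale (°C)
    ndd_half: float = 400.0         # logistic midpoint of the NDD0 response (°C·day)
    ndd_scale: float = 120.0

    # --- allometry and stem threshold -------------------------------------
    height_max_m: float = 15.0      # asymptotic tree height
    allom_k: float = 0.0302         # h = h_max·(1 − exp(−k·basal_cm)); 1.3 m at ~3 cm
    breast_height_m: float = 1.3

    # --- competition -------------------------------------------------------
    density_cell_m: float = 0.5     # density-field grid cell
    influence_r0_m: float = 0.6     # kernel radius intercept
    influence_r_per_h: float = 0.25 # + per metre of tree height
    influence_r_max_m: float = 3.0
    comp_growth: float = 0.30       # growth reduction 1/(1 + comp_growth·DI)
    comp_fecundity: float = 0.20
    comp_establish: float = 1.20    # germination suppression exp(−comp_establish·DI)

    # --- seed production and dispersal -------------------------------------
    maturation_height_mean_m: float = 2.5
    maturation_height_sd_m: float = 0.6
    maturation_height_min_m: float = 1.3
    fecundity_max: float = 8.0     # seeds per mature tree per year at saturation
    fecundity_d_half_cm: float = 4.0
    fall_velocity_ms: float = 0.8   # larch seed terminal fall speed

    # --- establishment ------------------------------------------------------
    germination_p0: float = 0.03    # warm-limit germination probability per year
    t_est_half: float = 10.4        # logistic midpoint for germination (°C July)
    t_est_scale: float = 0.4
    ald_min_cm: float = 10.0        # minimum active-layer depth for rooting
    seedling_basal_cm: float = 0.05 # initial basal diameter of a germinant

    # --- mortality ----------------------------------------------------------
    background_mortality: float = 0.002
    cold_mort_coef: float = 0.50    # hazard per °C of July deficit below t_mort_ref
    t_mort_ref: float = 10.0
    cold_juvenile_scale_cm: float = 1.0  # cold hazard fades as exp(−basal/scale)
    dens_mort_coef: float = 0.12    # density hazard per DI unit, juveniles
    dens_juvenile_scale_cm: float = 3.0
    juvenile_mort: float = 0.10     # size hazard juvenile_mort·exp(−basal/0.3)
    juvenile_size_scale_cm: float = 0.3
    drought_index_min: float = 0.10 # hazard when precip/NDD0 falls below this
    drought_mort_coef: float = 0.30
    age_max: float = 500.0          # larch longevity scale
    age_mort_coef: float = 0.6
    age_mort_power: float = 8.0
    seed_mortality: float = 0.45    # constant, on-tree and on-ground alike
    seed_age_limit: int = 3         # ground seeds removed beyond this age

    # --- permafrost ----------------------------------------------------------
    edaphic_factor: float = 1.0     # cm per sqrt(°C·day), Stefan-type thaw depth


@dataclass(frozen=True)
class SimulationConfig:
    transect_length_km: float = 50.0
    transect_width_m: float = 20.0
    climate_node_spacing_km: float = 10.0
    stabilization_years: int = 200
    stabilization_loop_years: int = 30  # climate loop length during stabilization
    repeats: int = 3
    rng_seed: int = 0
    # boundary seeding
    initial_seed_count: int = 100_000  # per year, first `initial_seed_years`
    initial_seed_years: int = 50
    initial_seed_mean_m: float = 1000.0  # negative-exponential placement scale
    permanent_seeds_per_200km: int = 1000
    hinterland_stretch_m: float = 500.0
    hinterland_rate: float = 20_000.0   # max hinterland seed rain per year
    snapshot_interval: int = 10
    # process toggles (for property tests and experiments)
    enable_dispersal: bool = True
    enable_establishment: bool = True
    enable_mortality: bool = True
    enable_boundary_seeds: bool = True

    def desk_scaled(self) -> "SimulationConfig":
        """Desk-scale variant: initial-pulse and hinterland seed counts ÷100.

        The permanent background rate is already proportional to transect
        length and is left untouched.
        """
        return replace(
            self,
            initial_seed_count=max(1, self.initial_seed_count // 100),
            hinterland_rate=self.hinterland_rate / 100.0,
        )


def load_config(path) -> tuple[SimulationConfig, LifeCycleParams]:
    """Read the declarative YAML config (``simulator`` and ``lifecycle`` sections)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    sim = SimulationConfig(**data.get("simulator", {}))
    life = LifeCycleParams(**data.get("lifecycle", {}))
    return sim, life


def dump_config(sim: SimulationConfig, life: LifeCycleParams, path) -> None:
    Path(path).write_text(
        yaml.safe_dump({"simulator": asdict(sim), "lifecycle": asdict(life)}, sort_keys=False)
    )
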