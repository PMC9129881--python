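"""Life-cycle process operations and small-scale simulation dynamics."""

import numpy as np
import pytest

from tundraline.params import LifeCycleParams, SimulationConfig
from tundraline.simulator import (
    TreelineSimulator,
    background_seed_count,
    breast_height_diameter,
    competition_factor,
    compute_max_growth,
    density_field,
    disperse_seeds,
    establishment_probability,
    influence_radius,
    interpolate_node_climate,
    produce_seeds,
    run_simulation,
    tree_death_probability,
    tree_height,
    update_environment,
)
from tundraline.wind import synth_wind

from .conftest import constant_series

P = LifeCycleParams()


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


def test_empty_stand_gives_zero_field():
    env = update_environment([], [], [], [], [0.0, 0.0], P, 20.0, 1000.0)
    assert np.all(env.density_field == 0.0)


def test_zero_degree_days_give_zero_active_layer():
    env = update_environment([], [], [], [], [0.0, 0.0], P, 20.0, 1000.0)
    assert np.all(env.active_layer_depth == 0.0)
    env = update_environment([], [], [], [], [400.0], P, 20.0, 1000.0)
    assert np.isclose(env.active_layer_depth[0], P.edaphic_factor * 20.0)


def test_two_tree_field_matches_closed_form_kernel_sum():
    """Midpoint field value equals the hand-computed triangular-kernel sum
    of both trees (positions on cell centres so lookup is exact)."""
    basal = np.array([2.0, 4.0])
    height = tree_height(basal, P)
    x = np.array([5.25, 5.25])
    y = np.array([10.25, 11.25])  # 1 m apart along the transect
    field = density_field(x, y, basal, height, P, width_m=20.0, length_m=100.0)
    mid = (5.25, 10.75)
    r = influence_radius(height, P)
    expected = sum(b * max(0.0, 1.0 - 0.5 / ri) for b, ri in zip(basal, r))
    iy, ix = int(mid[1] / P.density_cell_m), int(mid[0] / P.density_cell_m)
    assert np.isclose(field[iy, ix], expected, rtol=1e-6)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


def test_growth_zero_below_cold_threshold():
    assert compute_max_growth(P.t_jul_cold - 0.1, 1000.0, P) == 0.0


def test_growth_saturates_on_warm_plateau():
    g = compute_max_growth(25.0, 5000.0, P)
    assert np.isclose(g, P.g_max_cm, rtol=1e-6)


def test_growth_monotone_in_july_temperature():
    t = np.linspace(P.t_jul_cold, 16.0, 40)
    g = compute_max_growth(t, 800.0, P)
    assert np.all(np.diff(g) >= 0)
    warmer = compute_max_growth(t + 2.0, 800.0, P)
    rising = (t > P.t_jul_cold + 0.2) & (t < 14.0)
    assert np.all(warmer[rising] > g[rising])


def test_competition_free_growth_equals_max():
    assert competition_factor(0.0, P) == 1.0


def test_extreme_competition_suppresses_growth_without_shrinkage():
    f = competition_factor(1e9, P)
    assert 0.0 < f < 1e-6  # increment → 0 but never negative


def test_allometry_closed_form():
    d = 3.0
    h = tree_height(d, P)
    assert np.isclose(h, P.height_max_m * (1 - np.exp(-P.allom_k * d)))
    assert breast_height_diameter(d, h, P) == 0.0 if h <= 1.3 else True
    d2 = 10.0
    h2 = tree_height(d2, P)
    assert np.isclose(breast_height_diameter(d2, h2, P), d2 * (1 - 1.3 / h2))


# ---------------------------------------------------------------------------
# node-climate interpolation
# ---------------------------------------------------------------------------


def test_interpolation_on_node_returns_node_value():
    vals = np.array([10.0, 12.0, 14.0])
    assert interpolate_node_climate(10_000.0, [0.0, 10.0, 20.0], vals) == 12.0


def test_interpolation_midpoint():
    assert interpolate_node_climate(5_000.0, [0.0, 10.0], [10.0, 12.0]) == 11.0


def test_interpolation_matches_hand_weights():
    rng = np.random.default_rng(5)
    node_km = np.arange(6) * 10.0
    vals = rng.normal(size=6)
    y = rng.uniform(0, 50_000, size=100)
    got = interpolate_node_climate(y, node_km, vals)
    idx = np.clip((y // 10_000).astype(int), 0, 4)
    w = (y - idx * 10_000) / 10_000
    np.testing.assert_allclose(got, vals[idx] * (1 - w) + vals[idx + 1] * w, rtol=1e-12)


# ---------------------------------------------------------------------------
# dispersal
# ---------------------------------------------------------------------------


def test_calm_air_drops_seeds_at_parent():
    rng = np.random.default_rng(0)
    x, y = disperse_seeds(
        [10.0], [500.0], [5.0], [200], np.zeros(50), np.full(50, 90.0), P, 20.0, rng
    )
    assert np.allclose(x, 10.0) and np.allclose(y, 500.0)


def test_east_west_wrap_only():
    rng = np.random.default_rng(1)
    # strong easterly transport from a parent at the east margin
    x, y = disperse_seeds(
        [19.9], [500.0], [10.0], [500], np.full(10, 8.0), np.full(10, 90.0), P, 20.0, rng
    )
    assert np.all((x >= 0.0) & (x < 20.0))  # wrapped back in
    assert np.allclose(y, 500.0, atol=1e-6)  # pure-east wind never moves y


def test_median_distance_matches_ballistic_analytic():
    """Empirical median flight distance vs h·median(speed)/v_f at n = 1e5."""
    n = 100_000
    h, scale, shape = 10.0, 5.0, 2.0
    wind = synth_wind(n, weibull_scale=scale, weibull_shape=shape, rng_seed=3)
    rng = np.random.default_rng(4)
    x, y = disperse_seeds(
        [5e8], [50_000.0], [h], [n],
        wind["speed_ms"].to_numpy(), wind["direction_deg"].to_numpy(), P, 1e9, rng,
    )
    dist = np.hypot(x - 5e8, y - 50_000.0)
    med_speed = scale * np.log(2.0) ** (1.0 / shape)
    med = h * med_speed / P.fall_velocity_ms
    # SE of the sample median via the Weibull density at its median
    f_med = (shape / scale) * (np.log(2.0)) ** ((shape - 1) / shape) * 0.5
    se = (h / P.fall_velocity_ms) / (2.0 * f_med * np.sqrt(n))
    assert abs(np.median(dist) - med) < 3 * se


# ---------------------------------------------------------------------------
# production / establishment / mortality
# ---------------------------------------------------------------------------


def test_immature_trees_produce_nothing():
    rng = np.random.default_rng(0)
    c = produce_seeds([1.0], [2.5], [2.0], [0.0], [1.0], P, rng)
    assert c[0] == 0


def test_cold_year_stops_production():
    rng = np.random.default_rng(0)
    c = produce_seeds([5.0], [2.5], [8.0], [0.0], [0.0], P, rng)
    assert c[0] == 0


def test_competition_reduces_expected_fecundity():
    rng = np.random.default_rng(0)
    n = 20_000
    free = produce_seeds(np.full(n, 5.0), np.full(n, 2.5), np.full(n, 8.0),
                         np.zeros(n), np.ones(n), P, rng)
    crowded = produce_seeds(np.full(n, 5.0), np.full(n, 2.5), np.full(n, 8.0),
                            np.full(n, 20.0), np.ones(n), P, rng)
    assert free.sum() > crowded.sum()


def test_establishment_probability_bounds_and_gate():
    p_warm = establishment_probability(14.0, 0.0, 30.0, P)
    p_cold = establishment_probability(2.0, 0.0, 30.0, P)
    assert 0.0 <= p_cold < 1e-8 and 0.0 < p_warm <= P.germination_p0
    assert establishment_probability(14.0, 0.0, P.ald_min_cm - 1.0, P) == 0.0


def test_realized_germination_matches_binomial_expectation():
    """1e5 ground seeds at fixed conditions germinate within 3 SE of n·p."""
    n = 100_000
    forcing = constant_series(2, (2000, 2002), 13.0)
    cfg = SimulationConfig(
        transect_length_km=10.0, stabilization_years=0, enable_boundary_seeds=False,
        enable_mortality=False, rng_seed=5,
    )
    sim = TreelineSimulator(cfg, P, forcing, wind=synth_wind(100, rng_seed=0))
    rng = np.random.default_rng(6)
    sim.sx = rng.uniform(0, 20, n)
    sim.sy = rng.uniform(0, 10_000, n)
    sim.s_age = np.zeros(n, dtype=np.int64)
    ald = P.edaphic_factor * np.sqrt(
        float(sim.aux["ndd0"][0, 0])
    )
    p = float(establishment_probability(13.0, 0.0, ald, P))
    sim.run_year(0)
    germ = len(sim.tx)
    se = np.sqrt(n * p * (1 - p))
    assert abs(germ - n * p) < 3 * se


def test_benign_conditions_floor_at_background_mortality():
    p = tree_death_probability(10.0, 50.0, 0.0, 12.0, 0.5, P)
    assert np.isclose(p, P.background_mortality)


def test_ground_seed_survival_closed_form():
    """Constant seed mortality 0.5 over 3 years leaves (1-0.5)^3 = 12.5 %."""
    import dataclasses

    n = 100_000
    params = dataclasses.replace(P, seed_mortality=0.5, seed_age_limit=10)
    forcing = constant_series(2, (2000, 2003), -20.0)  # too cold to germinate
    cfg = SimulationConfig(
        transect_length_km=10.0, stabilization_years=0, enable_boundary_seeds=False,
        rng_seed=8,
    )
    sim = TreelineSimulator(cfg, params, forcing, wind=synth_wind(100, rng_seed=0))
    sim.sx = np.random.default_rng(9).uniform(0, 20, n)
    sim.sy = np.random.default_rng(10).uniform(0, 10_000, n)
    sim.s_age = np.zeros(n, dtype=np.int64)
    for i in range(3):
        sim.run_year(i)
    expected = n * 0.125
    se = np.sqrt(n * 0.125 * 0.875)
    assert abs(len(sim.sx) - expected) < 3 * se


def test_realized_tree_death_fraction_matches_probability():
    n = 100_000
    basal = np.full(n, 0.4)
    p = float(tree_death_probability(0.4, 20.0, 5.0, 9.2, 0.5, P))
    assert 0.01 < p < 0.9
    rng = np.random.default_rng(11)
    died = (rng.random(n) < tree_death_probability(basal, 20.0, 5.0, 9.2, 0.5, P)).sum()
    se = np.sqrt(n * p * (1 - p))
    assert abs(died - n * p) < 3 * se


# ---------------------------------------------------------------------------
# boundary seed introduction
# ---------------------------------------------------------------------------


def test_background_seed_rate_is_exact():
    assert background_seed_count(SimulationConfig(transect_length_km=200.0)) == 1000
    assert background_seed_count(SimulationConfig(transect_length_km=400.0)) == 2000
    assert background_seed_count(SimulationConfig(transect_length_km=50.0)) == 250


def test_initial_pulse_placement_matches_exponential_mean():
    n = 100_000
    cfg = SimulationConfig(
        transect_length_km=1000.0,  # long enough that clipping is negligible
        initial_seed_count=n,
        initial_seed_mean_m=1000.0,
        permanent_seeds_per_200km=0,
        hinterland_rate=0.0,
        stabilization_years=0,
        rng_seed=12,
    )
    forcing = constant_series(101, (2000, 2001), -20.0)
    sim = TreelineSimulator(cfg, P, forcing, wind=synth_wind(100, rng_seed=0))
    sim.introduce_boundary_seeds(stab_year=0, year_idx=0)
    se = 1000.0 / np.sqrt(n)
    assert abs(sim.sy.mean() - 1000.0) < 3 * se


# ---------------------------------------------------------------------------
# whole-run properties
# ---------------------------------------------------------------------------


def _warm_forcing(n_nodes=2, years=(2000, 2049)):
    return constant_series(n_nodes, years, 13.0)


def test_population_conserved_without_birth_and_death():
    cfg = SimulationConfig(
        transect_length_km=10.0, stabilization_years=0, enable_establishment=False,
        enable_mortality=False, enable_boundary_seeds=False, rng_seed=1,
    )
    forcing = _warm_forcing()
    sim = TreelineSimulator(cfg, P, forcing, wind=synth_wind(100, rng_seed=0))
    rng = np.random.default_rng(2)
    sim._add_trees(rng.uniform(0, 20, 500), rng.uniform(0, 10_000, 500))
    res = sim.run()
    main = res.log[res.log.phase == "main"]
    assert (main.n_trees == 500).all()


def test_same_seed_gives_bit_identical_snapshots():
    cfg = SimulationConfig(transect_length_km=10.0, stabilization_years=20, rng_seed=33)
    forcing = _warm_forcing()
    wind = synth_wind(500, rng_seed=3)
    a = run_simulation(cfg, forcing, wind=wind, repeat=1)
    b = run_simulation(cfg, forcing, wind=wind, repeat=1)
    assert len(a.snapshots) == len(b.snapshots)
    for sa, sb in zip(a.snapshots, b.snapshots):
        np.testing.assert_array_equal(sa.y_m, sb.y_m)
        np.testing.assert_array_equal(sa.basal_cm, sb.basal_cm)


def test_disabling_dispersal_freezes_the_front():
    """Without dispersal (and no boundary input) no tree can appear beyond
    the initial northernmost position."""
    cfg = SimulationConfig(
        transect_length_km=10.0, stabilization_years=0, enable_dispersal=False,
        enable_mortality=False, enable_boundary_seeds=False, rng_seed=4,
    )
    forcing = _warm_forcing()
    sim = TreelineSimulator(cfg, P, forcing, wind=synth_wind(100, rng_seed=0))
    rng = np.random.default_rng(5)
    sim._add_trees(rng.uniform(0, 20, 300), rng.uniform(0, 4000, 300))
    front0 = sim.ty.max()
    res = sim.run()
    assert sim.ty.max() == front0
    assert res.log.n_trees.iloc[-1] == 300  # establishment had nothing to work on


def test_positions_stay_inside_transect():
    cfg = SimulationConfig(transect_length_km=5.0, stabilization_years=30, rng_seed=6)
    forcing = _warm_forcing()
    sim = TreelineSimulator(cfg, P, forcing, wind=synth_wind(500, rng_seed=7))
    sim.run()
    assert np.all((sim.tx >= 0) & (sim.tx < cfg.transect_width_m))
    assert np.all((sim.ty >= 0) & (sim.ty <= 5000.0))
    assert np.all((sim.sy >= 0) & (sim.sy <= 5000.0))


def test_warm_stand_reaches_quasi_stationary_density():
    """200 warm years on a 5-km transect: the final 50-year tree-density
    trend is flat relative to the mean (stabilization property)."""
    from tundraline.forcing import synth_instrumental

    cfg = SimulationConfig(transect_length_km=5.0, stabilization_years=0, rng_seed=7)
    forcing = synth_instrumental(
        2, years=(2000, 2199), latitudinal_gradient=0.5, base_t_jul=13.0, rng_seed=9
    )
    res = run_simulation(cfg, forcing, wind=synth_wind(2000, rng_seed=8))
    main = res.log[res.log.phase == "main"].tail(50)
    trees = main.n_trees.to_numpy(dtype=float)
    slope = np.polyfit(np.arange(50), trees, 1)[0]
    assert abs(slope * 50) < 0.2 * trees.mean()
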