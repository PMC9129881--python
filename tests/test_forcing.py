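"""Forcing construction: proxy extension, calibration, monthly assembly,
scenario appending and regional offsets."""

import numpy as np
import pytest

from tundraline.climate import MonthlyClimateSeries
from tundraline.forcing import (
    AnnualProxySeries,
    RegionOffsets,
    ScenarioSpec,
    append_scenario,
    apply_region_offsets,
    assemble_monthly_preinstrumental,
    calibrate_to_instrumental,
    extend_proxy_series,
    synth_instrumental,
    synth_scenario_curve,
)

from .conftest import constant_series


def _proxy(years, values):
    values = np.asarray(values, dtype=float)
    return AnnualProxySeries(np.arange(years[0], years[1] + 1), values, np.ones_like(values))


# ---------------------------------------------------------------------------
# proxy extension
# ---------------------------------------------------------------------------


def test_extended_span_arithmetic():
    ref = _proxy((1700, 1799), np.arange(100.0))
    out = extend_proxy_series(ref, block_len=25, rng_seed=0, target_span=(501, 550))
    assert out.years[0] == 501 and out.years[-1] == 550 and len(out.years) == 50


def test_constant_reference_gives_constant_extension():
    ref = _proxy((1700, 1799), np.full(100, 7.5))
    out = extend_proxy_series(ref, rng_seed=42)
    assert np.all(out.value == 7.5)


def test_blocks_are_contiguous_reference_segments():
    """Each aligned 25-year output block must equal one of the 76 possible
    contiguous 25-year reference segments (brute-force scan)."""
    ref = _proxy((1700, 1799), np.arange(1.0, 101.0))
    out = extend_proxy_series(ref, block_len=25, preindustrial_cutoff=1800, rng_seed=3)
    segments = [ref.value[s : s + 25] for s in range(76)]
    for b0 in range(0, len(out.value) - 24, 25):
        block = out.value[b0 : b0 + 25]
        assert any(np.array_equal(block, seg) for seg in segments)


def test_reference_shorter_than_block_rejected():
    ref = _proxy((1780, 1799), np.arange(20.0))
    with pytest.raises(ValueError, match="block_len"):
        extend_proxy_series(ref, block_len=25)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def test_identity_regression_recovers_slope_one():
    inst = constant_series(2, (1901, 1998), 0.0)
    rng = np.random.default_rng(0)
    anomalies = rng.normal(0, 1, inst.n_years)
    inst.temp += anomalies[None, :, None]
    proxy = _proxy((1901, 1998), inst.annual_mean_temp()[0])
    cal = calibrate_to_instrumental(proxy, inst)
    assert np.allclose(cal.temp_slope, 1.0, atol=1e-9)
    assert np.allclose(cal.temp_intercept, 0.0, atol=1e-9)


def test_linear_proxy_recovered_against_hand_ols():
    """proxy = 2·T + 3 exactly: inverse slope 0.5, checked against the
    closed-form least-squares solution on five points."""
    temps = np.array([-3.0, -1.0, 0.0, 2.0, 4.0])
    inst = constant_series(1, (1901, 1905), 0.0)
    inst.temp[0] = temps[:, None]
    proxy = _proxy((1901, 1905), 2.0 * temps + 3.0)
    cal = calibrate_to_instrumental(proxy, inst, overlap=(1901, 1905))
    x, y = proxy.value, temps
    slope_hand = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    inter_hand = y.mean() - slope_hand * x.mean()
    assert np.isclose(cal.temp_slope[0], 0.5, atol=1e-12)
    assert np.isclose(cal.temp_slope[0], slope_hand, atol=1e-12)
    assert np.isclose(cal.temp_intercept[0], inter_hand, atol=1e-12)


def test_noise_free_limit_converges_to_truth():
    rng = np.random.default_rng(1)
    inst = constant_series(1, (1901, 1998), 0.0)
    anom = rng.normal(0, 1.0, inst.n_years)
    inst.temp += anom[None, :, None]
    truth_slope = -2.0
    for sigma, tol in [(0.1, 0.2), (1e-6, 1e-5)]:
        proxy_vals = (inst.annual_mean_temp()[0] - 1.0) / truth_slope
        proxy = _proxy((1901, 1998), proxy_vals + rng.normal(0, sigma, inst.n_years))
        cal = calibrate_to_instrumental(proxy, inst)
        assert np.isclose(cal.temp_slope[0], truth_slope, atol=tol * abs(truth_slope) * 3)


def test_zero_variance_proxy_refused():
    inst = constant_series(1, (1901, 1998), 0.0)
    proxy = _proxy((1901, 1998), np.full(98, 5.0))
    with pytest.raises(ValueError, match="variance"):
        calibrate_to_instrumental(proxy, inst)


# ---------------------------------------------------------------------------
# monthly assembly
# ---------------------------------------------------------------------------


def test_assembled_annual_means_match_targets_exactly():
    inst = synth_instrumental(3, years=(1901, 2005), rng_seed=7)
    proxy = _proxy((1901, 1998), np.random.default_rng(2).normal(size=98))
    cal = calibrate_to_instrumental(proxy, inst)
    extended = _proxy((501, 1900), np.random.default_rng(3).normal(size=1400))
    means = cal.predict(extended)
    out = assemble_monthly_preinstrumental(means, inst, rng_seed=11)
    np.testing.assert_allclose(out.annual_mean_temp(), means.temp_mean, atol=1e-9)
    np.testing.assert_allclose(out.annual_precip(), means.precip_total, rtol=1e-9)


def test_additive_shift_semantics():
    """A target mean 2 °C above the sampled block's mean shifts every month
    of that block by exactly +2 °C."""
    inst = synth_instrumental(1, years=(1901, 1915), rng_seed=0)
    from tundraline.forcing import AnnualMeans

    target = AnnualMeans(
        node_km=inst.node_km,
        years=np.arange(501, 516),
        temp_mean=inst.annual_mean_temp() + 2.0,
        precip_total=inst.annual_precip(),
    )
    out = assemble_monthly_preinstrumental(target, inst, block_len=15, rng_seed=0)
    # with a single possible source block the mapping is the identity
    np.testing.assert_allclose(out.temp, inst.temp + 2.0, atol=1e-9)
    np.testing.assert_allclose(out.precip, inst.precip, rtol=1e-9)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def base_series():
    return synth_instrumental(2, years=(1901, 2005), rng_seed=4)


def test_cooling_mode_restores_20th_century_july(base_series):
    out = append_scenario(base_series, ScenarioSpec("RCP4.5", "cooling"), rng_seed=0)
    m_post = out.slice_years(2501, 3000).july().mean(axis=1)
    m_ref = out.slice_years(1901, 1978).july().mean(axis=1)
    assert np.all(np.abs(m_post - m_ref) < 0.01)


def test_continued_mode_copies_2301_2500_block(base_series):
    out = append_scenario(base_series, ScenarioSpec("RCP8.5", "continued"), rng_seed=0)
    a = out.slice_years(2501, 2700).july()
    b = out.slice_years(2301, 2500).july()
    np.testing.assert_array_equal(a, b)


def test_rcp26star_is_half_the_rcp26_anomaly():
    c26 = synth_scenario_curve("RCP2.6")
    c26s = synth_scenario_curve("RCP2.6*")
    np.testing.assert_allclose(c26s["anomaly"], 0.5 * c26["anomaly"], rtol=1e-12)
    i2100 = int(np.nonzero(c26["year"] == 2100)[0][0])
    assert np.isclose(c26s["anomaly"][i2100] / c26["anomaly"][i2100], 0.5)


def test_scenario_ordering_of_midcentury_july_anomaly(base_series):
    """Mean 2050–2100 July anomaly must order RCP2.6* < 2.6 < 4.5 < 8.5."""
    means = {}
    base_july = base_series.slice_years(1976, 2005).july().mean()
    for sid in ("RCP2.6*", "RCP2.6", "RCP4.5", "RCP8.5"):
        out = append_scenario(base_series, ScenarioSpec(sid), rng_seed=9)
        means[sid] = out.slice_years(2050, 2100).july().mean() - base_july
    assert means["RCP2.6*"] < means["RCP2.6"] < means["RCP4.5"] < means["RCP8.5"]


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError, match="scenario"):
        ScenarioSpec("RCP6.0")


# ---------------------------------------------------------------------------
# regional offsets
# ---------------------------------------------------------------------------


def test_zero_offsets_are_identity(small_forcing):
    out = apply_region_offsets(small_forcing, RegionOffsets("null"))
    np.testing.assert_allclose(out.temp, small_forcing.temp, atol=1e-12)
    np.testing.assert_allclose(out.precip, small_forcing.precip, rtol=1e-12)


def test_chukotka_defaults_shift_july(small_forcing):
    out = apply_region_offsets(small_forcing, RegionOffsets.for_region("Chukotka"))
    np.testing.assert_allclose(out.july() - small_forcing.july(), 4.30, atol=1e-9)
    np.testing.assert_allclose(out.january() - small_forcing.january(), 4.46, atol=1e-9)
    np.testing.assert_allclose(
        out.annual_precip() - small_forcing.annual_precip(), 8.2, atol=1e-9
    )


def test_precipitation_clamped_at_zero_total():
    s = constant_series(1, (2000, 2000), 0.0, precip_mm=10.0)
    # offset exactly equal to the annual total: every month clamps to zero
    out = apply_region_offsets(s, RegionOffsets("dry", d_p_year=-120.0))
    assert np.all(out.precip == 0.0)
    # overshooting the total warns and still clamps
    with pytest.warns(UserWarning, match="clamp"):
        out = apply_region_offsets(s, RegionOffsets("drier", d_p_year=-150.0))
    assert np.all(out.precip == 0.0)


# ---------------------------------------------------------------------------
# synthetic instrumental generator
# ---------------------------------------------------------------------------


def test_gradient_sets_mean_july_difference():
    s = synth_instrumental(6, latitudinal_gradient=1.0, rng_seed=0)
    jul = s.july().mean(axis=1)
    assert np.isclose(jul[0] - jul[5], 0.5, atol=0.05)  # 50 km at 1 °C/100 km


def test_same_seed_reproduces_series():
    a = synth_instrumental(3, rng_seed=13)
    b = synth_instrumental(3, rng_seed=13)
    np.testing.assert_array_equal(a.temp, b.temp)
    np.testing.assert_array_equal(a.precip, b.precip)


def test_zero_noise_is_exactly_periodic(flat_forcing):
    assert np.all(flat_forcing.temp[:, 1:, :] == flat_forcing.temp[:, :-1, :])
    assert np.all(flat_forcing.precip[:, 1:, :] == flat_forcing.precip[:, :-1, :])
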