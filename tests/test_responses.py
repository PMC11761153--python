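"""Thermal response curves: pointwise values, shapes, orderings."""

import numpy as np
import pytest

from locustdyn import (
    AllahyariParams,
    GaussianFecundityParams,
    MortalityWindowParams,
    TemperatureForcing,
    adult_mortality,
    allahyari_rate,
    build_thermal_param_set,
    gaussian_fecundity,
    mortality_window,
    seasonal_temperature,
)
from locustdyn.responses import (
    EGG_HATCH,
    EGG_MORTALITY_GREGARIOUS,
    EGG_MORTALITY_SOLITARIOUS,
    FECUNDITY_SOLITARIOUS,
    curve_to_frame,
)

EGG = AllahyariParams(P=0.2658, n=1.5818, m=0.5, Tmin=15.1, Tmax=42.9187)


class TestGaussianFecundity:
    @pytest.mark.parametrize(
        "params, T, expected",
        [
            # maximum attained at the optimum
            (GaussianFecundityParams(4.4444, 30, 8), 30.0, 4.4444),
            (GaussianFecundityParams(1.5556, 30, 8), 30.0, 1.5556),
            # one-width point is Emax/e
            (GaussianFecundityParams(4.4444, 30, 8), 38.0, 4.4444 / np.e),
            # hand computation: exponent (16/8)^2 = 4
            (GaussianFecundityParams(1.5556, 30, 8), 46.0, 1.5556 * np.exp(-4.0)),
        ],
    )
    def test_pointwise(self, params, T, expected):
        assert gaussian_fecundity(params, T) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_and_unimodal(self):
        p = FECUNDITY_SOLITARIOUS
        d = np.linspace(0.1, 20, 40)
        assert np.allclose(gaussian_fecundity(p, p.Topt + d), gaussian_fecundity(p, p.Topt - d))
        vals = gaussian_fecundity(p, p.Topt + d)
        assert np.all(np.diff(vals) < 0)  # strictly decreasing away from Topt
        assert np.max(gaussian_fecundity(p, np.linspace(0, 60, 500))) <= p.Emax + 1e-12


class TestAllahyari:
    @pytest.mark.parametrize("T, expected", [
        (15.1, 0.0),       # x = 0 at the lower lethal bound
        (42.9187, 0.0),    # 1 - x^m = 0 at the upper bound
        (10.0, 0.0),       # clamped below the window
        (50.0, 0.0),       # clamped above the window
    ])
    def test_boundary_zeros(self, T, expected):
        assert allahyari_rate(EGG, T) == expected

    def test_independent_scalar_computation_at_30C(self):
        x = (30 - 15.1) / (42.9187 - 15.1)
        expected = 0.2658 * x**1.5818 * (1 - x**0.5)
        got = allahyari_rate(EGG, 30.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.0265, abs=5e-4)

    def test_unique_interior_maximum_nonnegative(self):
        grid = np.linspace(EGG.Tmin, EGG.Tmax, 2000)
        vals = allahyari_rate(EGG, grid)
        assert np.all(vals >= 0)
        peak = int(np.argmax(vals))
        assert 0 < peak < len(grid) - 1
        # increasing before the peak, decreasing after: single interior mode
        assert np.all(np.diff(vals[: peak + 1]) >= -1e-15)
        assert np.all(np.diff(vals[peak:]) <= 1e-15)


class TestMortalityWindow:
    def test_interior_plateau_is_one_minus_M(self):
        p = MortalityWindowParams(M=0.5, Q=1.5, Tmin=15, Tmax=35)
        assert mortality_window(p, 25.0) == pytest.approx(0.5, abs=2e-3)

    def test_M_above_one_clamps_to_zero_in_interior(self):
        p = MortalityWindowParams(M=1.19, Q=1.5, Tmin=15, Tmax=35)
        assert mortality_window(p, 25.0) == 0.0

    def test_lower_bound_value_by_hand(self):
        # window product is ~2 at the lower lethal bound
        p = MortalityWindowParams(M=0.5, Q=1.5, Tmin=15, Tmax=35)
        assert mortality_window(p, 15.0) == pytest.approx(1 - 0.5 * np.e**-1, abs=1e-3)

    def test_u_shape_and_saturation(self):
        p = EGG_MORTALITY_GREGARIOUS
        grid = np.linspace(p.Tmin - 5 * p.Q, p.Tmax + 5 * p.Q, 1500)
        vals = mortality_window(p, grid)
        assert np.all((vals >= 0) & (vals <= 1))
        mn = int(np.argmin(vals))
        assert np.all(np.diff(vals[: mn + 1]) <= 1e-12)
        assert np.all(np.diff(vals[mn:]) >= -1e-12)
        assert mortality_window(p, p.Tmin - 30) == pytest.approx(1.0, abs=1e-6)

    def test_gregarious_eggs_die_more_than_solitarious(self):
        # lower M means higher mortality pointwise
        grid = np.linspace(5, 50, 200)
        greg = mortality_window(EGG_MORTALITY_GREGARIOUS, grid)
        sol = mortality_window(EGG_MORTALITY_SOLITARIOUS, grid)
        assert np.all(greg >= sol - 1e-12)

    def test_as_printed_variant_is_unclamped_diagnostic(self):
        p = MortalityWindowParams(M=0.5, Q=1.5, Tmin=15, Tmax=35, variant="as_printed")
        # verbatim expression: 1 - M*exp(product); product >= 1 so value < 0
        assert mortality_window(p, 25.0) < 0


class TestAdultMortality:
    @pytest.mark.parametrize("baseline", [0.0083, 0.0111])
    def test_minimum_equals_baseline(self, baseline):
        w = MortalityWindowParams(M=1.0, Q=1.5, Tmin=20, Tmax=40)
        grid = np.linspace(20, 40, 2001)
        vals = adult_mortality(baseline, w, grid)
        assert np.min(vals) == pytest.approx(baseline, rel=1e-9)

    def test_saturates_at_one_beyond_lethal_bounds(self):
        w = MortalityWindowParams(M=1.0, Q=1.5, Tmin=20, Tmax=40)
        assert adult_mortality(0.0083, w, -10.0) == pytest.approx(1.0, abs=1e-6)
        assert adult_mortality(0.0083, w, 70.0) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_baseline_outside_unit_interval_rejected(self, bad):
        w = MortalityWindowParams(M=1.0, Q=1.5, Tmin=20, Tmax=40)
        with pytest.raises(ValueError):
            adult_mortality(bad, w, 30.0)


class TestThermalParamSet:
    def test_all_constant_set_is_temperature_independent(self, baseline):
        ts = build_thermal_param_set({})
        assert ts.is_constant()
        r20, r40 = ts.rates(20.0), ts.rates(40.0)
        assert r20 == r40
        assert r20["phi"] == baseline.phi

    def test_single_curve_config(self):
        ts = build_thermal_param_set(
            {"sigma": {"family": "allahyari", "P": 0.2658, "n": 1.5818, "m": 0.5,
                       "Tmin": 15.1, "Tmax": 42.9187}})
        assert ts.rates(30.0)["sigma"] == pytest.approx(allahyari_rate(EGG, 30.0), rel=1e-12)
        assert ts.rates(30.0)["sigma"] == pytest.approx(0.0265, abs=5e-4)

    def test_evaluation_over_forcing_cycle_bounded_periodic(self):
        ts = build_thermal_param_set({
            "phi": {"family": "gaussian", "Emax": 4.4444, "Topt": 30, "Tw": 8},
            "sigma": {"family": "allahyari", "P": 0.2658, "n": 1.5818, "m": 0.5,
                      "Tmin": 15.1, "Tmax": 42.9187},
            "mu_e": {"family": "mortality_window", "M": 0.91, "Q": 1.5,
                     "Tmin": 15.1, "Tmax": 42.9187},
        })
        f = TemperatureForcing(T0=28, T1=6, omega=1, kappa=30, variant="additive")
        ts_days = np.linspace(0, 365, 200)
        for name in ("phi", "sigma", "mu_e", "mu_s"):
            vals = np.array([ts.rates(seasonal_temperature(f, t))[name] for t in ts_days])
            shifted = np.array([ts.rates(seasonal_temperature(f, t + 365))[name] for t in ts_days])
            assert np.all(np.isfinite(vals)) and np.all(vals >= 0)
            assert np.allclose(vals, shifted, atol=1e-12)

    @pytest.mark.parametrize("config, match", [
        ({"sigma": {"family": "unknown_family", "P": 1}}, "sigma"),
        ({"phi": {"family": "gaussian", "Emax": 1}}, "phi"),
        ({"not_a_rate": 0.1}, "not_a_rate"),
    ])
    def test_configuration_errors_name_the_symbol(self, config, match):
        with pytest.raises(ValueError, match=match):
            build_thermal_param_set(config)


def test_curve_csv_export_columns():
    df = curve_to_frame(EGG_HATCH, np.linspace(10, 50, 9))
    assert list(df.columns) == ["T_celsius", "rate_per_day"]
    assert len(df) == 9
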