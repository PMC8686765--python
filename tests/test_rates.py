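"""Rate, yield and percent arithmetic on time courses and printed tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atpwaste.rates import (
    TimeCourse,
    carbon_yield,
    fit_growth_rate,
    percent_change,
    rates_from_timecourse,
    specific_rate_arrest,
    specific_rate_growth,
    yield_regression,
)


def _exp_culture(mu=0.3, x0=0.1, times=None):
    t = np.arange(0.0, 6.0) if times is None else np.asarray(times)
    return TimeCourse(pd.DataFrame({
        "time_h": t,
        "biomass_gDW_l": x0 * np.exp(mu * t),
        "glc": np.full_like(t, 20.0),
    }))


class TestGrowthRate:
    def test_noiseless_exponential_recovered_exactly(self):
        mu, r2 = fit_growth_rate(_exp_culture(mu=0.3))
        assert mu == pytest.approx(0.3, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_biomass_has_zero_slope(self):
        tc = TimeCourse(pd.DataFrame({
            "time_h": [0.0, 1.0, 2.0, 3.0],
            "biomass_gDW_l": [0.5] * 4,
            "glc": [20.0] * 4,
        }))
        mu, _ = fit_growth_rate(tc)
        assert mu == pytest.approx(0.0, abs=1e-14)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_growth_rate(_exp_culture(times=[0.0, 1.0]))

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0.0, 3.5, 8)
        x = 0.1 * np.exp(0.3 * t) * np.exp(rng.normal(0, 0.02, len(t)))
        tc = TimeCourse(pd.DataFrame({
            "time_h": t, "biomass_gDW_l": x, "glc": np.full(len(t), 20.0),
        }))
        mu, _ = fit_growth_rate(tc)
        assert mu == pytest.approx(0.3, abs=0.02)

    def test_od420_conversion(self):
        tc = TimeCourse(pd.DataFrame({
            "time_h": [0.0, 1.0, 2.0], "od420": [1.0, 2.0, 4.0],
            "glc": [20.0, 15.0, 10.0],
        }))
        assert tc.biomass[0] == pytest.approx(0.22)


class TestSpecificRates:
    def test_growth_formula(self):
        assert specific_rate_growth(0.2, 0.0, 10.0, 0.1, 0.6) == \
            pytest.approx(4.0)

    def test_no_metabolite_change_gives_zero(self):
        assert specific_rate_growth(0.2, 5.0, 5.0, 0.1, 0.6) == 0.0

    def test_zero_biomass_change_redirects_to_arrest_formula(self):
        with pytest.raises(ValueError, match="growth-arrest"):
            specific_rate_growth(0.2, 0.0, 10.0, 0.5, 0.5)

    def test_arrest_formula(self):
        assert specific_rate_arrest(0.0, 4.4, 0.44, 1.0) == \
            pytest.approx(10.0)

    def test_arrest_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            specific_rate_arrest(0.0, 4.4, 0.44, 0.0)


class TestYields:
    def _culture(self, slope):
        t = np.arange(0.0, 5.0)
        glc = 20.0 - 2.0 * t
        return TimeCourse(pd.DataFrame({
            "time_h": t, "biomass_gDW_l": 0.1 * np.exp(0.2 * t),
            "glc": glc, "lac": slope * (20.0 - glc),
        }))

    def test_stoichiometric_series_recovers_slope(self):
        # homolactate limit of the growth-arrested high-expression strain
        assert yield_regression(self._culture(1.74), "lac") == \
            pytest.approx(1.74, abs=1e-12)

    def test_flat_product_gives_zero_yield(self):
        assert yield_regression(self._culture(0.0), "lac") == 0.0

    def test_no_glucose_consumed_rejected(self):
        tc = TimeCourse(pd.DataFrame({
            "time_h": [0.0, 1.0, 2.0], "biomass_gDW_l": [0.1] * 3,
            "glc": [20.0] * 3, "lac": [0.0, 1.0, 2.0],
        }))
        with pytest.raises(ValueError, match="glucose"):
            yield_regression(tc, "lac")

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(8)
        tc = self._culture(1.74)
        noisy = tc.data.assign(
            lac=np.maximum(
                tc.data["lac"] + rng.normal(0, 0.1, len(tc.data)), 0.0))
        assert yield_regression(TimeCourse(noisy), "lac") == \
            pytest.approx(1.74, abs=0.05)


class TestPercentChange:
    @pytest.mark.parametrize("value, ref, expected", [
        (16.38, 14.05, 16.6),   # low-copy strain uptake gain
        (17.70, 15.02, 17.8),   # medium-copy strain uptake gain
        (5.13, 12.93, -60.3),   # high-copy strain collapse
        (3.0, 3.0, 0.0),
    ])
    def test_values(self, value, ref, expected):
        assert round(percent_change(value, ref), 1) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0), st.floats(0.1, 100.0))
    def test_antisymmetry_identity(self, a, b):
        # 100 (a-b)/b == -(100 (b-a)/a) * a/b
        lhs = percent_change(a, b)
        rhs = -percent_change(b, a) * a / b
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestCarbonYield:
    def test_low_copy_strain_growth_yields(self):
        yields = {"eth": 0.770, "ace": 0.790, "for": 1.542,
                  "lac": 0.161, "suc": 0.106}
        assert round(carbon_yield(yields), 2) == 0.93

    def test_zero_yields(self):
        assert carbon_yield(dict.fromkeys(
            ("eth", "ace", "for", "lac", "suc"), 0.0)) == 0.0

    def test_pure_homolactate_recovers_all_carbon(self):
        yields = dict.fromkeys(("eth", "ace", "for", "suc"), 0.0)
        yields["lac"] = 2.0
        assert carbon_yield(yields) == pytest.approx(1.0)

    def test_missing_analyte_named(self):
        with pytest.raises(ValueError, match="suc"):
            carbon_yield({"eth": 0.5, "ace": 0.5, "for": 1.0, "lac": 0.1})


def test_summary_roundtrip_matches_direct_formulas():
    mu, x0 = 0.25, 0.05
    t = np.linspace(0.0, 4.0, 9)
    x = x0 * np.exp(mu * t)
    r_glc, r_eth = 12.0, 9.0
    glc = 25.0 - (r_glc / mu) * (x - x0)
    eth = (r_eth / mu) * (x - x0)
    tc = TimeCourse(pd.DataFrame({
        "time_h": t, "biomass_gDW_l": x, "glc": glc, "eth": eth,
    }))
    summary = rates_from_timecourse(tc, mode="growth")
    assert summary.mu == pytest.approx(mu, abs=1e-9)
    assert -summary.rates["glc"] == pytest.approx(r_glc, abs=1e-9)
    assert summary.rates["eth"] == pytest.approx(r_eth, abs=1e-9)
    assert summary.yields["eth"] == pytest.approx(r_eth / r_glc, abs=1e-9)


def test_time_course_validation():
    with pytest.raises(ValueError, match="increasing"):
        TimeCourse(pd.DataFrame({
            "time_h": [0.0, 2.0, 1.0], "biomass_gDW_l": [0.1] * 3,
            "glc": [20.0] * 3,
        }))
    with pytest.raises(ValueError, match="biomass"):
        TimeCourse(pd.DataFrame({
            "time_h": [0.0, 1.0], "biomass_gDW_l": [0.1, 0.0],
            "glc": [20.0] * 2,
        }))
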