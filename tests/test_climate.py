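"""Climate suitability indices: beta temperature response, FAO-56 ET0,
precipitation band, day length, and season aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deltacrop import climate
from deltacrop.climate import (
    DEFAULT_STAGES,
    StageParams,
    beta_exponent,
    comprehensive_index,
    crop_water_requirement,
    day_length,
    reference_et0,
    season_suitability,
    sunshine_suitability,
    temperature_suitability,
    water_suitability,
)

from oracles import day_length_scan_oracle, fao56_et0_oracle

EMERGENCE = DEFAULT_STAGES[0]


class TestBetaExponent:
    @pytest.mark.parametrize(
        "tl,to,th,expected",
        [(11.0, 30.0, 42.0, 0.63), (5.7, 22.5, 42.0, 1.16)],
    )
    def test_printed_stage_values(self, tl, to, th, expected):
        assert round(beta_exponent(tl, to, th), 2) == expected

    def test_midpoint_optimum_gives_unity(self):
        assert beta_exponent(10.0, 25.0, 40.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("tl,to,th", [(30, 11, 42), (11, 42, 30), (30, 30, 42)])
    def test_violated_ordering_raises(self, tl, to, th):
        with pytest.raises(ValueError):
            beta_exponent(tl, to, th)


class TestTemperatureSuitability:
    def test_optimum_normalizes_to_one(self):
        assert temperature_suitability(30.0, EMERGENCE) == pytest.approx(1.0)

    @pytest.mark.parametrize("t", [45.0, 42.0, 10.0, 11.0, -5.0])
    def test_zero_outside_cardinal_interval(self, t):
        assert temperature_suitability(t, EMERGENCE) == 0.0

    def test_closed_form_value(self):
        # independent numeric evaluation with B = 12/19
        b = 12.0 / 19.0
        expected = (20.0 - 11.0) * (42.0 - 20.0) ** b / ((30.0 - 11.0) * 12.0**b)
        assert temperature_suitability(20.0, EMERGENCE) == pytest.approx(expected)
        assert temperature_suitability(20.0, EMERGENCE) == pytest.approx(0.695, abs=1e-3)

    @given(st.floats(min_value=-20.0, max_value=60.0))
    def test_bounded_in_unit_interval(self, t):
        assert 0.0 <= temperature_suitability(t, EMERGENCE) <= 1.0

    def test_unimodal_around_optimum(self):
        ts = np.linspace(11.0, 42.0, 400)
        f = temperature_suitability(ts, EMERGENCE)
        peak = np.argmax(f)
        assert np.all(np.diff(f[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(f[peak:]) <= 1e-12)
        assert ts[peak] == pytest.approx(30.0, abs=0.1)

    def test_vectorized_matches_scalar(self):
        ts = np.array([15.0, 25.0, 35.0])
        vec = temperature_suitability(ts, EMERGENCE)
        assert vec == pytest.approx([temperature_suitability(t, EMERGENCE) for t in ts])


class TestWaterSuitability:
    def test_inside_band_is_one(self):
        assert water_suitability(100.0, 100.0) == 1.0
        assert water_suitability(70.0, 100.0) == 1.0
        assert water_suitability(130.0, 100.0) == 1.0

    def test_half_band_below(self):
        assert water_suitability(35.0, 100.0) == pytest.approx(0.5)

    def test_half_band_above(self):
        assert water_suitability(260.0, 100.0) == pytest.approx(0.5)

    def test_monotone_below_band_and_above_band(self):
        et_c = 80.0
        rs = np.linspace(0.0, 0.7 * et_c, 50)
        f = [water_suitability(r, et_c) for r in rs]
        assert np.all(np.diff(f) >= 0)
        rs = np.linspace(1.3 * et_c, 10 * et_c, 50)
        f = [water_suitability(r, et_c) for r in rs]
        assert np.all(np.diff(f) <= 0)

    def test_zero_etc_is_domain_error(self):
        with pytest.raises(ValueError):
            water_suitability(10.0, 0.0)


class TestSunshineAndComprehensive:
    @pytest.mark.parametrize("s,so,expected", [(11.0, 11.0, 1.0), (0.0, 11.0, 0.0), (5.5, 11.0, 0.5), (14.0, 11.0, 1.0)])
    def test_sunshine_piecewise_linear(self, s, so, expected):
        assert sunshine_suitability(s, so) == pytest.approx(expected)

    def test_sunshine_nonpositive_threshold_raises(self):
        with pytest.raises(ValueError):
            sunshine_suitability(5.0, 0.0)

    @pytest.mark.parametrize(
        "f_t,f_r,f_s,expected",
        [(1.0, 1.0, 1.0, 1.0), (0.0, 0.5, 0.9, 0.0), (0.8, 0.7, 0.76, 0.752)],
    )
    def test_geometric_mean(self, f_t, f_r, f_s, expected):
        assert comprehensive_index(f_t, f_r, f_s) == pytest.approx(expected, abs=1e-3)

    def test_out_of_range_input_raises(self):
        with pytest.raises(ValueError):
            comprehensive_index(1.2, 0.5, 0.5)


class TestDayLength:
    def test_equator_is_twelve_hours(self):
        for doy in (1, 100, 200, 300):
            assert day_length(0.0, doy) == pytest.approx(12.0, abs=0.1)

    def test_equinox_is_twelve_hours(self):
        assert day_length(37.5, 80) == pytest.approx(12.0, abs=0.2)

    @pytest.mark.parametrize("doy", [1, 80, 172, 266, 355])
    def test_matches_bruteforce_elevation_scan(self, doy):
        assert day_length(37.5, doy) == pytest.approx(day_length_scan_oracle(37.5, doy), abs=0.05)

    def test_polar_latitude_out_of_scope(self):
        with pytest.raises(ValueError):
            day_length(70.0, 172)


class TestReferenceET0:
    def test_agrees_with_independent_fao56_oracle_on_fuzzed_records(self, rng):
        for _ in range(100):
            t_mean = rng.uniform(-5, 35)
            spread = rng.uniform(2, 10)
            rec = dict(
                t_mean=t_mean,
                t_min=t_mean - spread,
                t_max=t_mean + spread,
                rh=rng.uniform(0.2, 0.95),
                u2=rng.uniform(0, 8),
                sunshine_hours=rng.uniform(0, 13),
                lat=rng.uniform(30, 45),
                doy=int(rng.integers(1, 366)),
                elevation=rng.uniform(0, 100),
            )
            mine = reference_et0(**rec)
            ref = fao56_et0_oracle(
                rec["t_mean"], rec["t_min"], rec["t_max"], rec["rh"], rec["u2"],
                rec["sunshine_hours"], rec["lat"], rec["doy"], rec["elevation"],
            )
            assert mine == pytest.approx(ref, abs=0.01)

    def test_nonnegative_and_finite(self, rng):
        for _ in range(50):
            v = reference_et0(
                rng.uniform(-10, 40), rng.uniform(-15, 20), rng.uniform(25, 45),
                rng.uniform(0.1, 1.0), rng.uniform(0, 10), rng.uniform(0, 12),
                37.5, int(rng.integers(1, 366)), 5.0,
            )
            assert v >= 0.0 and math.isfinite(v)

    def test_higher_vapor_pressure_deficit_raises_et0(self):
        common = dict(t_mean=25.0, t_min=18.0, t_max=32.0, u2=2.0, sunshine_hours=9.0, lat=37.5, doy=180)
        assert reference_et0(rh=0.4, **common) > reference_et0(rh=0.8, **common)

    def test_missing_humidity_is_explicit_error(self):
        with pytest.raises(ValueError, match="rh"):
            reference_et0(25.0, 18.0, 32.0, float("nan"), 2.0, 9.0, 37.5, 180)


class TestCropWaterRequirement:
    def test_sum_times_kc(self):
        assert crop_water_requirement([4.0] * 10, 1.15) == pytest.approx(46.0)

    def test_zero_kc(self):
        assert crop_water_requirement([4.0] * 10, 0.0) == 0.0

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            crop_water_requirement([], 1.0)

    def test_default_stage_kc_values(self):
        assert [s.k_c for s in DEFAULT_STAGES] == [0.45, 1.15, 1.05]


def _constant_weather(t_by_stage, precip_by_stage=None, sunshine=11.0, year=2001):
    """One season of daily weather, constant within each stage window."""
    rows = []
    for stage, t in zip(DEFAULT_STAGES, t_by_stage):
        lo, hi = stage.date_window
        for doy in range(lo, hi + 1):
            rows.append(
                dict(
                    date=pd.Timestamp(year, 1, 1) + pd.Timedelta(days=doy - 1),
                    t_mean=t, t_min=t - 5, t_max=t + 5,
                    precip=0.0, sunshine=sunshine, u2=2.0, rh=0.6,
                    lat=37.5, elevation=5.0,
                )
            )
    df = pd.DataFrame(rows)
    if precip_by_stage is not None:
        doy = df["date"].dt.dayofyear
        for stage, p in zip(DEFAULT_STAGES, precip_by_stage):
            lo, hi = stage.date_window
            df.loc[(doy >= lo) & (doy <= hi), "precip"] = p
    return df


class TestSeasonSuitability:
    def test_all_optimal_weather_scores_one_everywhere(self):
        optimal_t = [s.t_o for s in DEFAULT_STAGES]
        probe = season_suitability(_constant_weather(optimal_t))
        # feed back each stage's ET_c as uniform daily precipitation
        daily_p = [et / s.n_days for et, s in zip(probe.et_c, DEFAULT_STAGES)]
        res = season_suitability(_constant_weather(optimal_t, precip_by_stage=daily_p))
        assert res.f_t == pytest.approx([1.0] * 3)
        assert res.f_r == pytest.approx([1.0] * 3)
        assert res.f_s == pytest.approx([1.0] * 3)
        assert res.f_trs == pytest.approx([1.0] * 3)
        assert res.season == pytest.approx(1.0)

    def test_insensitive_stage_scores_full_sunshine_at_zero_sun(self):
        df = _constant_weather([s.t_o for s in DEFAULT_STAGES], sunshine=0.0)
        res = season_suitability(df)
        # stages 1 and 3 are photoperiod-insensitive, stage 2 is sensitive
        assert res.f_s[0] == 1.0 and res.f_s[2] == 1.0
        assert res.f_s[1] == 0.0

    def test_comprehensive_is_geometric_mean_per_stage(self):
        df = _constant_weather([25.0, 28.0, 20.0], sunshine=8.0)
        res = season_suitability(df)
        assert res.f_trs == pytest.approx((res.f_t * res.f_r * res.f_s) ** (1 / 3))
        assert np.all((res.f_trs >= 0) & (res.f_trs <= 1))

    def test_gap_in_stage_window_raises(self):
        df = _constant_weather([s.t_o for s in DEFAULT_STAGES])
        df = df[df["date"].dt.dayofyear != 150]
        with pytest.raises(ValueError, match="gap"):
            season_suitability(df)

    def test_daylength_threshold_option_runs(self):
        df = _constant_weather([s.t_o for s in DEFAULT_STAGES], sunshine=10.0)
        res = season_suitability(df, sunshine_threshold="daylength")
        assert 0.0 <= res.f_s[1] <= 1.0

    def test_synthetic_delta_climate_mean_season_in_sanity_band(self):
        # 50 station-years under the default study conditions
        from deltacrop.synthetic import SyntheticConfig, generate_weather

        wx = generate_weather(SyntheticConfig(seed=5))
        wx["year"] = pd.to_datetime(wx["date"]).dt.year
        vals = [
            season_suitability(grp).season for _, grp in wx.groupby(["station", "year"])
        ]
        assert 0.6 <= float(np.mean(vals)) <= 0.9


class TestStageParams:
    def test_table_beta_consistency_invariant(self):
        for s in DEFAULT_STAGES:
            printed = {"emergence-heading": 0.63, "heading-flowering": 0.63, "flowering-maturity": 1.16}
            assert abs(round(s.beta, 2) - printed[s.name]) < 0.005

    def test_invalid_cardinal_ordering_rejected(self):
        with pytest.raises(ValueError):
            StageParams("bad", (1, 10), t_l=30.0, t_o=20.0, t_h=42.0, k_c=1.0)


def test_period_means_groups_years():
    yearly = pd.DataFrame(
        {
            "station": ["A"] * 4 + ["B"] * 4,
            "year": [1980, 1981, 1990, 1991] * 2,
            "season": [0.8, 0.6, 0.4, 0.2, 1.0, 0.8, 0.6, 0.4],
        }
    )
    pm = climate.period_means(yearly, [(1980, 1989), (1990, 1999)])
    a80 = pm[(pm["station"] == "A") & (pm["period"] == "1980-1989")]["season"].iloc[0]
    assert a80 == pytest.approx(0.7)
    assert len(pm) == 4
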