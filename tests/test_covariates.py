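"""Covariate construction: GDD, precipitation, daylength, filtering, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoclim import (
    CovariateConfig,
    apply_scaler,
    build_covariate_table,
    compute_avg_precip,
    compute_gdd,
    daylength,
    filter_records,
    fit_scaler,
)
from phenoclim.covariates import invert_scaler

from conftest import make_records

# geosphere::daylength 1.5-20 reference values (CBM formula, p = 0.8333 deg)
GEOSPHERE_REF = [
    (0.0, 80, 12.1111067813),
    (80.0, 172, 24.0),
    (34.1, 172, 14.4302821138),
    (34.1, 355, 9.8763033073),
    (-34.1, 80, 12.1416099254),
    (35.5, 1, 9.7966835311),
    (33.0, 200, 14.0721684191),
]


class TestGDD:
    def test_direct_formula(self):
        assert compute_gdd([10, 12, 8], 5) == pytest.approx(15.0)

    def test_cold_window_floors_to_zero(self):
        assert compute_gdd([3, 4, 2], 5) == 0.0

    def test_total_floor_variant(self):
        # mixed window: per-day keeps the warm day, total floor cancels it
        assert compute_gdd([10, 0, 0], 5, gdd_floor="per_day") == pytest.approx(5.0)
        assert compute_gdd([10, 0, 0], 5, gdd_floor="on_total") == 0.0

    def test_brute_force_oracle(self, rng):
        temps = rng.uniform(-5, 35, size=120)
        expected = sum(max(0.0, t - 5.0) for t in temps)
        assert compute_gdd(temps, 5.0) == pytest.approx(expected, abs=1e-9)

    def test_missing_temperature_rejected(self):
        with pytest.raises(ValueError, match="incomplete climate"):
            compute_gdd([10.0, np.nan, 12.0], 5.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        temps=st.lists(st.floats(-20, 45), min_size=5, max_size=40),
        day=st.integers(0, 4),
        bump=st.floats(0.01, 10),
    )
    def test_warming_any_day_never_decreases_gdd(self, temps, day, bump):
        t = np.array(temps)
        before = compute_gdd(t, 5.0)
        t[day % len(t)] += bump
        assert compute_gdd(t, 5.0) >= before


class TestAvgPrecip:
    def test_zero_and_arithmetic(self):
        assert compute_avg_precip([0, 0, 0]) == 0.0
        assert compute_avg_precip([1, 2, 3]) == pytest.approx(2.0)

    def test_brute_force_oracle(self, rng):
        p = rng.exponential(2.0, size=120)
        assert compute_avg_precip(p) == pytest.approx(sum(p) / 120, abs=1e-9)

    def test_negative_precip_rejected(self):
        with pytest.raises(ValueError):
            compute_avg_precip([1.0, -0.1])


class TestDaylength:
    def test_equator_near_twelve_hours(self):
        assert daylength(0.0, 80) == pytest.approx(12.0, abs=0.2)

    def test_polar_day_clamps_to_24(self):
        assert daylength(80.0, 172) == 24.0

    def test_polar_night_clamps_to_0(self):
        assert daylength(85.0, 355) == 0.0

    @pytest.mark.parametrize("lat,doy,hours", GEOSPHERE_REF)
    def test_matches_reference_implementation(self, lat, doy, hours):
        assert daylength(lat, doy) == pytest.approx(hours, abs=0.01)

    def test_hemisphere_symmetry_at_equinox(self):
        for lat in (10.0, 34.1, 55.0):
            assert daylength(lat, 80) == pytest.approx(daylength(-lat, 80), abs=0.2)

    def test_latitude_out_of_range(self):
        with pytest.raises(ValueError):
            daylength(91.0, 100)

    def test_bounds_hold_everywhere(self, rng):
        lats = rng.uniform(-90, 90, 500)
        doys = rng.integers(1, 367, 500)
        out = daylength(lats, doys)
        assert np.all((out >= 0.0) & (out <= 24.0))


class TestFilterRecords:
    def _six(self):
        return make_records(
            [
                ("a", "2020-05-01", "flowers_present", "whole"),
                ("b", "2020-05-02", "flowers_present", "partial"),
                ("c", "2020-05-03", "flowers_absent", "whole"),
                ("d", "2020-05-04", "flowers_absent", "whole"),
                ("e", "2020-05-05", "flowers_absent", "partial"),
                ("f", "2020-05-06", "flowers_absent", "uncertain"),
            ]
        )

    def test_confirmed_absence_rule(self):
        kept, log = filter_records(self._six())
        assert sorted(kept["record_id"]) == ["a", "b", "c", "d"]
        assert log["dropped_partial_absence"] == 1
        assert log["dropped_uncertain_absence"] == 1

    def test_partial_plant_presence_retained(self):
        kept, _ = filter_records(self._six())
        assert "b" in set(kept["record_id"])  # flowers in frame need no whole plant

    def test_incomplete_climate_window_dropped(self, constant_climate):
        recs = make_records(
            [
                ("early", "2020-02-01", "flowers_absent", "whole"),  # <120 d of record
                ("late", "2020-06-01", "flowers_absent", "whole"),
            ]
        )
        kept, log = filter_records(recs, constant_climate, CovariateConfig(window_days=120))
        assert list(kept["record_id"]) == ["late"]
        assert log["dropped_incomplete_climate"] == 1

    def test_filtering_is_idempotent(self):
        once, _ = filter_records(self._six())
        twice, log = filter_records(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log["n_retained"] == log["n_input"]


class TestBuildCovariateTable:
    def test_constant_climate_hand_values(self, constant_climate):
        recs = make_records([("r1", "2020-06-01", "flowers_present", "whole")])
        cov = build_covariate_table(recs, constant_climate, CovariateConfig(window_days=30))
        assert cov.loc[0, "gdd"] == pytest.approx(300.0)  # 30 d x (15-5)
        assert cov.loc[0, "avg_precip"] == pytest.approx(1.0)
        assert cov.loc[0, "y"] == 1

    def test_daylength_independent_of_window(self, constant_climate):
        recs = make_records([("r1", "2020-06-01", "flowers_absent", "whole")])
        c30 = build_covariate_table(recs, constant_climate, CovariateConfig(window_days=30))
        c120 = build_covariate_table(recs, constant_climate, CovariateConfig(window_days=120))
        assert c30.loc[0, "daylength"] == c120.loc[0, "daylength"]
        assert c30.loc[0, "gdd"] == c120.loc[0, "gdd"] / 4  # constant climate

    def test_brute_force_recomputation(self, small_climate, small_observations):
        cfg = CovariateConfig(window_days=30)
        cov = build_covariate_table(small_observations.head(40), small_climate, cfg)
        clim = small_climate.set_index(["site", "date"])
        for _, row in cov.iterrows():
            days = pd.date_range(row["date"] - pd.Timedelta(days=30), periods=30, freq="D")
            sub = clim.loc[[(row["site"], d) for d in days]]
            tmean = (sub["tmin"].to_numpy() + sub["tmax"].to_numpy()) / 2
            assert row["gdd"] == pytest.approx(compute_gdd(tmean, 5.0), abs=1e-9)
            assert row["avg_precip"] == pytest.approx(
                compute_avg_precip(sub["precip"].to_numpy()), abs=1e-9
            )
            assert row["daylength"] == pytest.approx(
                daylength(row["latitude"], row["day_of_year"]), abs=1e-12
            )

    def test_window_is_strictly_before_observation(self, constant_climate):
        # window must not include the observation day: a record on the first
        # admissible date has exactly window_days prior days available
        recs = make_records([("r1", "2020-01-31", "flowers_absent", "whole")])
        cov = build_covariate_table(recs, constant_climate, CovariateConfig(window_days=30))
        assert len(cov) == 1
        recs_early = make_records([("r0", "2020-01-30", "flowers_absent", "whole")])
        assert len(build_covariate_table(recs_early, constant_climate, CovariateConfig(window_days=30))) == 0


class TestScaler:
    def test_closed_form_three_values(self):
        df = pd.DataFrame({"gdd": [1.0, 2.0, 3.0], "avg_precip": [0.0, 1.0, 2.0], "daylength": [9.0, 12.0, 15.0]})
        params = fit_scaler(df)
        out = apply_scaler(df, params)
        assert list(out["scaled_gdd"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_round_trip(self, rng):
        df = pd.DataFrame({"gdd": rng.uniform(0, 500, 50), "avg_precip": rng.uniform(0, 5, 50), "daylength": rng.uniform(9, 15, 50)})
        params = fit_scaler(df)
        back = invert_scaler(apply_scaler(df, params), params)
        for col in ("gdd", "avg_precip", "daylength"):
            assert np.allclose(back[col], df[col], atol=1e-12)

    def test_training_stats_fixed_under_shift(self, rng):
        train = pd.DataFrame({"gdd": rng.normal(100, 20, 200), "avg_precip": rng.normal(2, 0.5, 200), "daylength": rng.normal(12, 1, 200)})
        test = train + 50.0  # deliberate distribution shift
        params = fit_scaler(train)
        scaled_train = apply_scaler(train, params)
        scaled_test = apply_scaler(test, params)
        assert abs(scaled_train["scaled_gdd"].mean()) < 1e-10
        assert scaled_train["scaled_gdd"].std(ddof=1) == pytest.approx(1.0)
        assert scaled_test["scaled_gdd"].mean() > 1.0  # no leakage: shift visible

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"gdd": [1.0, 1.0, 1.0], "avg_precip": [0.0, 1.0, 2.0], "daylength": [9.0, 12.0, 15.0]})
        with pytest.raises(ValueError, match="gdd"):
            fit_scaler(df)
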