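"""Preprocessing rules: imputation, trimming, aggregation, outlier filter,
per-location yield trend, min-max scaling, unit conversion, block assembly."""

import numpy as np
import pandas as pd
import pytest

from yieldens import (
    FeaturePanel,
    SchemaError,
    aggregate_weather_periods,
    apply_minmax_scaler,
    apply_yield_trend,
    assemble_feature_blocks,
    convert_yield_units,
    drop_yield_outliers,
    fit_minmax_scaler,
    fit_yield_trend,
    impute_planting_progress,
    trim_out_of_season,
)
from yieldens.panel import progress_col, progress_cols, soil_cols, weather_cols
from yieldens.preprocess import ImputationError, UnitError, default_period_map


def _mini_progress_panel():
    """Three states, two years, 52-week progress rows with ND missing."""
    rows = []
    for state, base in [("ND", np.nan), ("SD", 40.0), ("MN", 60.0)]:
        for year in (1998, 1999):
            row = {"state": state, "county": "C1", "year": year, "yield": 100.0}
            for w in range(1, 53):
                row[progress_col(w)] = base if not np.isnan(base) else np.nan
            rows.append(row)
    return FeaturePanel(pd.DataFrame(rows))


class TestImputation:
    def test_midpoint_of_donors(self):
        panel = _mini_progress_panel()
        out = impute_planting_progress(panel, "ND", ("SD", "MN"), years=[1998, 1999])
        nd = out.df[out.df["state"] == "ND"]
        assert (nd[progress_cols()] == 50.0).all().all()

    def test_equal_donors_give_identity(self):
        panel = _mini_progress_panel()
        panel.df.loc[panel.df["state"] == "MN", progress_cols()] = 40.0
        out = impute_planting_progress(panel, "ND", ("SD", "MN"), years=[1998])
        nd98 = out.df[(out.df["state"] == "ND") & (out.df["year"] == 1998)]
        assert (nd98[progress_cols()] == 40.0).all().all()

    def test_no_missing_cells_is_noop(self, small_panel):
        states = small_panel.df["state"].unique()
        out = impute_planting_progress(
            small_panel, states[0], (states[1], states[1]), years=[2000]
        )
        pd.testing.assert_frame_equal(out.df, small_panel.df)

    def test_missing_donor_value_raises(self):
        panel = _mini_progress_panel()
        panel.df.loc[panel.df["state"] == "SD", progress_col(20)] = np.nan
        with pytest.raises(ImputationError, match="week"):
            impute_planting_progress(panel, "ND", ("SD", "MN"), years=[1998])

    def test_unknown_state_raises(self):
        with pytest.raises(KeyError):
            impute_planting_progress(_mini_progress_panel(), "XX", ("SD", "MN"), [1998])


class TestSeasonTrim:
    def test_default_window_retains_32_weeks(self, small_panel):
        out = trim_out_of_season(small_panel)
        for var in out.weather_vars:
            assert len(out.weather_columns(var)) == 32
        assert len(out.progress_columns()) == 32

    def test_full_year_window_is_identity(self, small_panel):
        out = trim_out_of_season(small_panel, (1, 52))
        pd.testing.assert_frame_equal(out.df, small_panel.df)

    def test_narrow_window_counts(self, small_panel):
        out = trim_out_of_season(small_panel, (10, 12))
        for var in out.weather_vars:
            assert len(out.weather_columns(var)) == 3

    def test_soil_and_keys_untouched(self, small_panel):
        out = trim_out_of_season(small_panel)
        pd.testing.assert_frame_equal(
            out.df[soil_cols() + ["state", "county", "year"]],
            small_panel.df[soil_cols() + ["state", "county", "year"]],
        )

    @pytest.mark.parametrize("window", [(0, 10), (20, 10), (1, 53)])
    def test_invalid_window_rejected(self, small_panel, window):
        with pytest.raises(ValueError):
            trim_out_of_season(small_panel, window)


class TestAggregation:
    def test_sum_and_mean_rules(self, small_panel):
        panel = trim_out_of_season(small_panel, (14, 16))
        period_map = {14: 1, 15: 1, 16: 1}
        df = panel.df.copy()
        df[["prcp_w14", "prcp_w15", "prcp_w16"]] = [10.0, 0.0, 5.0]
        df[["tmax_w14", "tmax_w15", "tmax_w16"]] = [20.0, 30.0, 25.0]
        out = aggregate_weather_periods(panel.copy(df=df), period_map)
        assert (out.df["agg_prcp_p1"] == 15.0).all()
        assert (out.df["agg_tmax_p1"] == 25.0).all()

    def test_single_week_period_is_identity(self, small_panel):
        panel = trim_out_of_season(small_panel, (20, 20))
        out = aggregate_weather_periods(panel, {20: 1})
        for var in panel.weather_vars:
            np.testing.assert_array_equal(
                out.df[f"agg_{var}_p1"], panel.df[f"{var}_w20"]
            )

    def test_annual_aggregate_added_per_variable(self, small_panel):
        panel = trim_out_of_season(small_panel)
        out = aggregate_weather_periods(panel)
        for var in panel.weather_vars:
            assert f"agg_{var}_annual" in out.df.columns
        np.testing.assert_allclose(
            out.df["agg_prcp_annual"],
            panel.df[panel.weather_columns("prcp")].sum(axis=1),
        )

    def test_unassigned_week_raises(self, small_panel):
        panel = trim_out_of_season(small_panel, (14, 20))
        with pytest.raises(ValueError, match="not assigned"):
            aggregate_weather_periods(panel, {w: 1 for w in range(14, 20)})

    def test_default_period_map_covers_season_in_four_blocks(self, small_panel):
        panel = trim_out_of_season(small_panel)
        pmap = default_period_map(panel)
        assert set(pmap) == set(range(14, 46))
        assert set(pmap.values()) == {1, 2, 3, 4}


class TestOutlierFilter:
    def _panel(self, yields):
        df = pd.DataFrame(
            {
                "state": "S01",
                "county": [f"C{i}" for i in range(len(yields))],
                "year": 2000,
                "yield": yields,
            }
        )
        return FeaturePanel(df)

    def test_strictly_below_threshold_removed(self):
        out, removed = drop_yield_outliers(self._panel([5.0, 10.0, 150.0]))
        assert removed == 1
        assert out.df["yield"].tolist() == [10.0, 150.0]

    def test_all_above_is_noop(self):
        panel = self._panel([11.0, 50.0])
        out, removed = drop_yield_outliers(panel)
        assert removed == 0
        pd.testing.assert_frame_equal(out.df, panel.df)

    def test_empty_panel_degenerate(self):
        out, removed = drop_yield_outliers(self._panel([]))
        assert removed == 0 and len(out) == 0

    def test_wrong_unit_rejected(self):
        panel = self._panel([500.0])
        panel.yield_unit = "kg/ha"
        with pytest.raises(UnitError):
            drop_yield_outliers(panel)


class TestYieldTrend:
    def _panel(self, years, yields, county="C1"):
        return FeaturePanel(
            pd.DataFrame(
                {"state": "S01", "county": county, "year": years, "yield": yields}
            )
        )

    def test_exact_line(self):
        models = fit_yield_trend(self._panel([1, 2, 3], [2.0, 4.0, 6.0]))
        m = models[("S01", "C1")]
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert m.slope == pytest.approx(2.0, abs=1e-9)

    def test_flat_trend(self):
        m = fit_yield_trend(self._panel([1, 2, 3], [5.0, 5.0, 5.0]))[("S01", "C1")]
        assert m.slope == pytest.approx(0.0, abs=1e-9)
        assert m.intercept == pytest.approx(5.0, abs=1e-9)

    def test_closed_form_coefficients(self):
        # OLS on years 2000-2003, yields (100,110,105,125): slope 7.0,
        # intercept mean(y) - 7*mean(year) = -13900.5 (hand-derived)
        years, yields = [2000, 2001, 2002, 2003], [100.0, 110.0, 105.0, 125.0]
        m = fit_yield_trend(self._panel(years, yields))[("S01", "C1")]
        assert m.slope == pytest.approx(7.0, abs=1e-9)
        assert m.intercept == pytest.approx(110.0 - 7.0 * 2001.5, abs=1e-6)
        # extrapolation to the next year follows the same line
        assert m.predict(2004) == pytest.approx(110.0 + 7.0 * 2.5, abs=1e-6)

    def test_apply_extrapolates(self):
        train = self._panel([1, 2, 3], [2.0, 4.0, 6.0])
        models = fit_yield_trend(train)
        test = self._panel([4], [999.0])
        out = apply_yield_trend(models, test)
        assert out.df["yield_trend"].iloc[0] == pytest.approx(8.0, abs=1e-9)

    def test_single_year_location_gets_flat_mean(self):
        m = fit_yield_trend(self._panel([2000], [42.0]))[("S01", "C1")]
        assert (m.intercept, m.slope) == (42.0, 0.0)

    def test_unseen_location_raises(self):
        models = fit_yield_trend(self._panel([1, 2, 3], [2.0, 4.0, 6.0]))
        with pytest.raises(KeyError, match="C9"):
            apply_yield_trend(models, self._panel([4], [0.0], county="C9"))

    def test_residuals_orthogonal_per_location(self, small_panel):
        models = fit_yield_trend(small_panel)
        out = apply_yield_trend(models, small_panel)
        resid = out.df["yield"] - out.df["yield_trend"]
        per_loc = resid.groupby([out.df["state"], out.df["county"]]).mean()
        assert (per_loc.abs() < 1e-9).all()


class TestUnitConversion:
    def test_known_conversion_values(self):
        assert convert_yield_units([15.74], "bu/acre->kg/ha")[0] == pytest.approx(
            988.0, abs=0.5
        )
        assert convert_yield_units([13.93], "bu/acre->kg/ha")[0] == pytest.approx(
            874.0, abs=0.5
        )

    def test_zero_and_roundtrip(self):
        assert convert_yield_units([0.0], "bu/acre->kg/ha")[0] == 0.0
        x = np.array([1.0, 100.0])
        back = convert_yield_units(
            convert_yield_units(x, "bu/acre->kg/ha"), "kg/ha->bu/acre"
        )
        np.testing.assert_allclose(back, x)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            convert_yield_units([1.0], "acre->ha")


class TestMinMaxScaler:
    def _panel(self, values):
        df = pd.DataFrame(
            {
                "state": "S01",
                "county": [f"C{i}" for i in range(len(values))],
                "year": 2000,
                "agg_x_p1": values,
                "yield": 1.0,
            }
        )
        return FeaturePanel(df)

    def test_linear_map(self):
        scaler = fit_minmax_scaler(self._panel([0.0, 5.0, 10.0]))
        out = apply_minmax_scaler(scaler, self._panel([0.0, 5.0, 10.0]))
        assert out.df["agg_x_p1"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_feature_maps_to_zero(self):
        scaler = fit_minmax_scaler(self._panel([7.0, 7.0]))
        out = apply_minmax_scaler(scaler, self._panel([7.0, 7.0]))
        assert (out.df["agg_x_p1"] == 0.0).all()

    def test_test_values_extrapolate_unclipped(self):
        scaler = fit_minmax_scaler(self._panel([0.0, 10.0]))
        out = apply_minmax_scaler(scaler, self._panel([12.0, -2.0]))
        assert out.df["agg_x_p1"].tolist() == [1.2, -0.2]

    def test_training_features_land_in_unit_interval(self, processed_split):
        train, _, fitted = processed_split
        block = train.df[fitted.scaler.columns].to_numpy()
        assert block.min() >= -1e-12 and block.max() <= 1 + 1e-12

    def test_fit_ignores_test_rows(self, small_panel):
        from yieldens import year_forward_split

        train_raw, _ = year_forward_split(small_panel, 2011)
        scaler = fit_minmax_scaler(train_raw)
        spiked = train_raw.copy()
        assert scaler.maxima.equals(fit_minmax_scaler(spiked).maxima)
        # bounds computed from train only: test-year extremes cannot move them
        assert set(scaler.columns) == set(train_raw.feature_columns())


class TestAssembleBlocks:
    def test_default_shapes(self, processed_split):
        train, _, _ = processed_split
        blocks = assemble_feature_blocks(train)
        assert blocks.weather.shape[1:] == (5, 32)
        assert blocks.soil.shape[1:] == (10, 10)
        assert blocks.other.shape[1] == 32 + 5 * 5 + 1  # progress + aggregates + trend

    def test_round_trip_reassembly(self, processed_split):
        train, _, _ = processed_split
        blocks = assemble_feature_blocks(train)
        row = 3
        rebuilt = np.concatenate(
            [blocks.weather[row].ravel(), blocks.soil[row].ravel()]
        )
        original = np.concatenate(
            [
                train.df.iloc[row][train.weather_columns()].to_numpy(dtype=float),
                train.df.iloc[row][train.soil_columns()].to_numpy(dtype=float),
            ]
        )
        np.testing.assert_array_equal(rebuilt, original)

    def test_missing_soil_columns_raise(self, processed_split):
        train, _, _ = processed_split
        broken = train.copy(df=train.df.drop(columns=["ph_d03"]))
        with pytest.raises(SchemaError):
            assemble_feature_blocks(broken)


class TestPipeline:
    def test_train_test_key_disjointness(self, processed_split):
        train, test, _ = processed_split
        train_keys = set(map(tuple, train.keys().to_numpy()))
        test_keys = set(map(tuple, test.keys().to_numpy()))
        assert not train_keys & test_keys

    def test_reapplying_noop_stage_is_bit_identical(self, small_panel):
        once = trim_out_of_season(small_panel)
        twice = trim_out_of_season(once, once.season)
        pd.testing.assert_frame_equal(once.df, twice.df)
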