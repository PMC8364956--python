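"""Panel preparation: imputation, season trimming, aggregation, outlier
filtering, per-location yield trend, min-max scaling, unit conversion and
block assembly.

All fitted transforms (trend models, scaler) are fitted on training records
only and applied unchanged to test records; the pipeline order is
impute → trim → aggregate → outlier-filter → trend → scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import (
    N_SOIL_DEPTHS,
    WEATHER_AGG,
    FeaturePanel,
    SchemaError,
    progress_col,
    weather_col,
)

#: kg/ha per bu/acre for corn at 56 lb/bushel.
KG_PER_HA_PER_BU_PER_ACRE = 62.77

#: Default in-season window (inclusive weeks).  32 retained weeks feed each
#: weather CNN branch.
DEFAULT_SEASON = (14, 45)


class ImputationError(ValueError):
    """A donor value needed for planting-progress imputation is missing."""


class UnitError(ValueError):
    """An operation received yields in the wrong unit."""


# ---------------------------------------------------------------------------
# planting-progress imputation
# ---------------------------------------------------------------------------

def impute_planting_progress(
    panel: FeaturePanel,
    target_state: str,
    donor_states: tuple[str, str],
    years,
) -> FeaturePanel:
    """Fill missing weekly progress for *target_state* in *years* with the
    arithmetic mean of the two donor states' values for the same week/year.

    Only missing (NaN) cells are touched; everything else is returned
    bit-identical.
    """
    df = panel.df
    for st in (target_state, *donor_states):
        if st not in set(df["state"]):
            raise KeyError(f"unknown state {st!r}")
    df = df.copy()
    cols = panel.progress_columns()
    years = set(years)
    mask = (df["state"] == target_state) & df["year"].isin(years)
    for year in sorted(df.loc[mask, "year"].unique()):
        rows = df.index[mask & (df["year"] == year)]
        donors = []
        for d in donor_states:
            drows = df[(df["state"] == d) & (df["year"] == year)]
            if drows.empty:
                raise ImputationError(f"donor {d} has no rows for year {year}")
            donors.append(drows.iloc[0][cols].astype(float))
        donor_mean = (donors[0] + donors[1]) / 2.0
        for col in cols:
            missing = rows[df.loc[rows, col].isna()]
            if len(missing):
                if np.isnan(donor_mean[col]):
                    raise ImputationError(
                        f"donor value missing for week {col!r}, year {year}"
                    )
                df.loc[missing, col] = donor_mean[col]
    return panel.copy(df=df)


# ---------------------------------------------------------------------------
# season trimming and period aggregation
# ---------------------------------------------------------------------------

def trim_out_of_season(
    panel: FeaturePanel, season_weeks: tuple[int, int] = DEFAULT_SEASON
) -> FeaturePanel:
    """Drop weather and planting-progress columns outside the growing season.

    Soil columns and keys are untouched.  The retained window is recorded on
    the returned panel so downstream stages know the weather input length.
    """
    start, end = season_weeks
    if not (1 <= start <= end <= 52):
        raise ValueError(f"invalid season window {season_weeks}")
    drop = []
    for w in panel.weeks:
        if w < start or w > end:
            drop.append(progress_col(w))
            drop.extend(weather_col(v, w) for v in panel.weather_vars)
    drop = [c for c in drop if c in panel.df.columns]
    return panel.copy(df=panel.df.drop(columns=drop), season=(start, end))


def default_period_map(panel: FeaturePanel, n_periods: int = 4) -> dict[int, int]:
    """Assign retained weeks to *n_periods* contiguous blocks of (near-)equal
    length — the "quarters" of the trimmed season."""
    weeks = list(panel.weeks)
    splits = np.array_split(np.asarray(weeks), n_periods)
    return {int(w): p + 1 for p, chunk in enumerate(splits) for w in chunk}


def aggregate_weather_periods(
    panel: FeaturePanel, period_map: dict[int, int] | None = None
) -> FeaturePanel:
    """Add per-period and annual weather aggregates as ``agg_*`` columns.

    Precipitation and radiation are summed within each period; temperatures
    and growing degree days are averaged row-wise.  Weekly columns are
    retained.
    """
    if period_map is None:
        period_map = default_period_map(panel)
    unassigned = [w for w in panel.weeks if w not in period_map]
    if unassigned:
        raise ValueError(f"weeks not assigned to any period: {unassigned}")
    df = panel.df.copy()
    new_cols = {}
    periods = sorted(set(period_map.values()))
    for var in panel.weather_vars:
        how = WEATHER_AGG[var]
        all_cols = [weather_col(var, w) for w in panel.weeks]
        for p in periods:
            cols = [weather_col(var, w) for w in panel.weeks if period_map[w] == p]
            block = df[cols]
            new_cols[f"agg_{var}_p{p}"] = block.sum(axis=1) if how == "sum" else block.mean(axis=1)
        block = df[all_cols]
        new_cols[f"agg_{var}_annual"] = block.sum(axis=1) if how == "sum" else block.mean(axis=1)
    return panel.copy(df=pd.concat([df, pd.DataFrame(new_cols, index=df.index)], axis=1))


# ---------------------------------------------------------------------------
# outlier filtering and unit conversion
# ---------------------------------------------------------------------------

def drop_yield_outliers(
    panel: FeaturePanel, threshold: float = 10.0
) -> tuple[FeaturePanel, int]:
    """Remove records with yield strictly below *threshold* bu/acre.

    Returns the filtered panel and the number of records removed.  The
    boundary value itself (exactly 10 bu/acre) is retained.
    """
    if panel.yield_unit != "bu/acre":
        raise UnitError("outlier threshold is defined in bu/acre; convert first")
    keep = panel.df["yield"] >= threshold
    removed = int((~keep).sum())
    return panel.copy(df=panel.df[keep].reset_index(drop=True)), removed


def convert_yield_units(values, direction: str) -> np.ndarray:
    """Convert yields between bu/acre and kg/ha (62.77 kg/ha per bu/acre)."""
    values = np.asarray(values, dtype=float)
    if direction == "bu/acre->kg/ha":
        return values * KG_PER_HA_PER_BU_PER_ACRE
    if direction == "kg/ha->bu/acre":
        return values / KG_PER_HA_PER_BU_PER_ACRE
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# per-location yield trend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendModel:
    """OLS fit of yield on calendar year for one (state, county) location."""

    intercept: float
    slope: float

    def predict(self, year) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(year, dtype=float)


def fit_yield_trend(train_panel: FeaturePanel) -> dict[tuple[str, str], TrendModel]:
    """Fit one yield-on-year OLS line per location, on training years only.

    Locations with fewer than two distinct years get slope 0 and intercept
    equal to their mean yield, so the trend feature stays defined everywhere.
    """
    models: dict[tuple[str, str], TrendModel] = {}
    for (state, county), grp in train_panel.df.groupby(["state", "county"], sort=True):
        years = grp["year"].to_numpy(dtype=float)
        y = grp["yield"].to_numpy(dtype=float)
        if len(np.unique(years)) < 2:
            models[(state, county)] = TrendModel(float(np.mean(y)), 0.0)
        else:
            slope, intercept = np.polyfit(years, y, 1)
            models[(state, county)] = TrendModel(float(intercept), float(slope))
    return models


def apply_yield_trend(
    models: dict[tuple[str, str], TrendModel], panel: FeaturePanel
) -> FeaturePanel:
    """Add ``yield_trend`` = b0_i + b1_i · year for every record.

    Future (test) years extrapolate the fitted line.  A location without a
    fitted model raises ``KeyError`` — the county roster is fixed across
    years, so an unseen location signals a split bug, not data to impute.
    """
    df = panel.df.copy()
    trends = np.empty(len(df))
    for i, (state, county, year) in enumerate(
        zip(df["state"], df["county"], df["year"])
    ):
        key = (state, county)
        if key not in models:
            raise KeyError(f"no trend model for location {key}")
        trends[i] = models[key].predict(year)
    df["yield_trend"] = trends
    return panel.copy(df=df)


# ---------------------------------------------------------------------------
# min-max scaling
# ---------------------------------------------------------------------------

@dataclass
class MinMaxScaler:
    """Per-feature min-max bounds observed on training data.

    Features are mapped to (x − min)/(max − min); training values land in
    [0, 1], test values may fall outside and are never clipped.  A constant
    feature (max = min) maps to 0.
    """

    minima: pd.Series
    maxima: pd.Series

    @property
    def columns(self) -> list[str]:
        return list(self.minima.index)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        span = (self.maxima - self.minima).replace(0.0, 1.0)
        df[self.columns] = (df[self.columns] - self.minima) / span
        return df

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.columns, "min": self.minima.values, "max": self.maxima.values})


def fit_minmax_scaler(train_panel: FeaturePanel) -> MinMaxScaler:
    """Record per-feature min/max over all independent variables of the
    training panel (the yield target is left unscaled)."""
    cols = train_panel.feature_columns()
    block = train_panel.df[cols]
    if not all(np.issubdtype(dt, np.number) for dt in block.dtypes):
        raise TypeError("non-numeric feature column in panel")
    return MinMaxScaler(block.min(axis=0), block.max(axis=0))


def apply_minmax_scaler(scaler: MinMaxScaler, panel: FeaturePanel) -> FeaturePanel:
    return panel.copy(df=scaler.transform(panel.df))


# ---------------------------------------------------------------------------
# block assembly for the network
# ---------------------------------------------------------------------------

@dataclass
class FeatureBlocks:
    """Model-ready input arrays split by network branch.

    ``weather``: (n, 5, L_w) — one length-L_w sequence per weather variable;
    ``soil``: (n, 10, 10) — one depth profile per soil variable;
    ``other``: (n, d) — planting progress + aggregates + yield_trend;
    ``y``: (n,) targets, in ``yield_unit``.
    """

    weather: np.ndarray
    soil: np.ndarray
    other: np.ndarray
    y: np.ndarray
    yield_unit: str

    def __len__(self) -> int:
        return self.weather.shape[0]

    def take(self, idx) -> "FeatureBlocks":
        idx = np.asarray(idx)
        return FeatureBlocks(
            self.weather[idx], self.soil[idx], self.other[idx], self.y[idx], self.yield_unit
        )


def assemble_feature_blocks(panel: FeaturePanel) -> FeatureBlocks:
    """Split a fully preprocessed panel into per-branch input arrays,
    preserving week order (weather) and depth order (soil)."""
    panel.require_blocks()
    df = panel.df
    n = len(df)
    L = len(list(panel.weeks))
    weather = np.empty((n, len(panel.weather_vars), L))
    for i, var in enumerate(panel.weather_vars):
        weather[:, i, :] = df[panel.weather_columns(var)].to_numpy()
    soil = np.empty((n, len(panel.soil_vars), N_SOIL_DEPTHS))
    for i, var in enumerate(panel.soil_vars):
        soil[:, i, :] = df[panel.soil_columns(var)].to_numpy()
    other_cols = panel.progress_columns() + panel.engineered_columns()
    other = df[other_cols].to_numpy(dtype=float)
    y = df["yield"].to_numpy(dtype=float) if "yield" in df.columns else np.full(n, np.nan)
    return FeatureBlocks(weather, soil, other, y, panel.yield_unit)


# ---------------------------------------------------------------------------
# pipeline convenience
# ---------------------------------------------------------------------------

@dataclass
class FittedTransforms:
    """Everything fitted on the training panel that test data must reuse."""

    trend_models: dict[tuple[str, str], TrendModel]
    scaler: MinMaxScaler
    season: tuple[int, int]
    n_outliers_removed: int

    def metadata_lines(self) -> list[str]:
        return [
            f"season_start={self.season[0]}",
            f"season_end={self.season[1]}",
            f"n_outliers_removed={self.n_outliers_removed}",
            f"n_scaled_features={len(self.scaler.columns)}",
        ]


def preprocess_train_test(
    train: FeaturePanel,
    test: FeaturePanel,
    season_weeks: tuple[int, int] = DEFAULT_SEASON,
    n_periods: int = 4,
) -> tuple[FeaturePanel, FeaturePanel, FittedTransforms]:
    """Run the full fixed-order pipeline, fitting transforms on train only.

    Test rows never influence the trend models or scaler bounds; the test
    panel is filtered with the same outlier rule so metrics are computed on
    the population the models target.
    """
    stages = []
    for p in (train, test):
        p = trim_out_of_season(p, season_weeks)
        p = aggregate_weather_periods(p, default_period_map(p, n_periods))
        p, removed = drop_yield_outliers(p)
        stages.append((p, removed))
    (train, n_removed), (test, _) = stages

    trend_models = fit_yield_trend(train)
    train = apply_yield_trend(trend_models, train)
    test = apply_yield_trend(trend_models, test)

    scaler = fit_minmax_scaler(train)
    train = apply_minmax_scaler(scaler, train)
    test = apply_minmax_scaler(scaler, test)
    fitted = FittedTransforms(trend_models, scaler, season_weeks, n_removed)
    return train, test, fitted
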