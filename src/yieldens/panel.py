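"""County-year feature panel: container, column conventions, CSV round-trip.

A panel is a flat table keyed by (state, county, year) holding four feature
blocks plus the yield target:

* planting progress — state-level weekly cumulative percentage planted,
  columns ``pp_w01 .. pp_w52``;
* weather — five variables by week, columns ``<var>_w01 .. <var>_w52``
  (after season trimming only the in-season weeks remain);
* soil — ten variables by ten profile depths, columns ``<var>_d01 .. _d10``,
  constant across years within a county;
* engineered — period aggregates (``agg_*``) and the per-location
  ``yield_trend`` covariate added during preprocessing.

The target column is ``yield``; its unit (bu/acre or kg/ha) travels with the
panel as metadata rather than in the column name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

KEY_COLS = ("state", "county", "year")
YIELD_COL = "yield"

WEATHER_VARS = ("prcp", "tmax", "tmin", "srad", "gdd")
#: aggregation rule per weather variable: totals are summed, temperatures averaged
WEATHER_AGG = {"prcp": "sum", "srad": "sum", "tmax": "mean", "tmin": "mean", "gdd": "mean"}

SOIL_VARS = (
    "bulk_wet",
    "bulk_dry",
    "clay",
    "paw",
    "paw_ll",
    "ksat",
    "om",
    "ph",
    "sand",
    "sat_wc",
)
N_SOIL_DEPTHS = 10
N_WEEKS = 52


def progress_col(week: int) -> str:
    return f"pp_w{week:02d}"


def weather_col(var: str, week: int) -> str:
    return f"{var}_w{week:02d}"


def soil_col(var: str, depth: int) -> str:
    return f"{var}_d{depth:02d}"


def progress_cols(weeks=range(1, N_WEEKS + 1)) -> list[str]:
    return [progress_col(w) for w in weeks]


def weather_cols(variables=WEATHER_VARS, weeks=range(1, N_WEEKS + 1)) -> list[str]:
    return [weather_col(v, w) for v in variables for w in weeks]


def soil_cols(variables=SOIL_VARS, depths=range(1, N_SOIL_DEPTHS + 1)) -> list[str]:
    return [soil_col(v, d) for v in variables for d in depths]


class SchemaError(ValueError):
    """A panel is missing columns or violates a block-shape contract."""


@dataclass
class FeaturePanel:
    """A county-year panel plus the metadata fitted transforms depend on.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per (state, county, year).
    yield_unit : str
        ``"bu/acre"`` or ``"kg/ha"``.
    season : tuple[int, int] | None
        Inclusive (start week, end week) once out-of-season columns have been
        trimmed; ``None`` for a raw 52-week panel.
    weather_vars, soil_vars : tuple[str, ...]
        Variable name rosters for the weather and soil blocks.
    """

    df: pd.DataFrame
    yield_unit: str = "bu/acre"
    season: tuple[int, int] | None = None
    weather_vars: tuple[str, ...] = WEATHER_VARS
    soil_vars: tuple[str, ...] = SOIL_VARS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in KEY_COLS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"panel missing key columns: {missing}")

    # -- block views ----------------------------------------------------
    @property
    def weeks(self) -> range:
        if self.season is None:
            return range(1, N_WEEKS + 1)
        return range(self.season[0], self.season[1] + 1)

    def progress_columns(self) -> list[str]:
        return [c for c in progress_cols(self.weeks) if c in self.df.columns]

    def weather_columns(self, var: str | None = None) -> list[str]:
        vs = (var,) if var is not None else self.weather_vars
        return [weather_col(v, w) for v in vs for w in self.weeks]

    def soil_columns(self, var: str | None = None) -> list[str]:
        vs = (var,) if var is not None else self.soil_vars
        return [soil_col(v, d) for v in vs for d in range(1, N_SOIL_DEPTHS + 1)]

    def engineered_columns(self) -> list[str]:
        out = [c for c in self.df.columns if c.startswith("agg_")]
        if "yield_trend" in self.df.columns:
            out.append("yield_trend")
        return out

    def feature_columns(self) -> list[str]:
        present = set(self.df.columns)
        return [
            c
            for c in (
                self.progress_columns()
                + self.weather_columns()
                + self.soil_columns()
                + self.engineered_columns()
            )
            if c in present
        ]

    def require_blocks(self) -> None:
        """Raise :class:`SchemaError` unless all expected block columns exist."""
        expect = self.progress_cols_expected() + self.weather_columns() + self.soil_columns()
        missing = [c for c in expect if c not in self.df.columns]
        if missing:
            raise SchemaError(f"panel missing {len(missing)} columns, e.g. {missing[:4]}")

    def progress_cols_expected(self) -> list[str]:
        return progress_cols(self.weeks)

    # -- conveniences ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def copy(self, df: pd.DataFrame | None = None, **changes) -> "FeaturePanel":
        return replace(self, df=self.df.copy() if df is None else df, **changes)

    def keys(self) -> pd.DataFrame:
        return self.df[list(KEY_COLS)]

    # -- CSV round-trip -------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "FeaturePanel":
        return cls(pd.read_csv(path), **kwargs)
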