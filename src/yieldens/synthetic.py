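"""Synthetic county-year panels with the schema the yield models expect.

The generator emulates the statistical structure the modelling pipeline
assumes about Corn Belt panel data, without touching any external source:

* a per-location linear technology trend in yield (intercept + slope × year),
* weekly weather as a smooth seasonal climatology plus AR(1) anomalies,
  whose season-mean anomaly feeds linearly into yield,
* static soil depth profiles per county with a mildly nonlinear (quadratic)
  contribution to yield,
* state-level cumulative planting-progress curves (logistic, non-decreasing,
  bounded in [0, 100]),
* i.i.d. Gaussian yield noise, and an optional small fraction of records
  with yield below 10 bu/acre to exercise the outlier filter.

Every generated panel is reproducible bit-for-bit from (schema, truth, seed),
and :func:`true_predictions` returns the noise-free conditional mean yield so
recovery tests can compare fitted models against the generating process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import (
    N_SOIL_DEPTHS,
    N_WEEKS,
    SOIL_VARS,
    WEATHER_VARS,
    FeaturePanel,
    SchemaError,
    progress_col,
    soil_col,
    weather_col,
)

# Seasonal climatology per weather variable: (annual mean, amplitude, phase
# week, floor).  Units: mm/day for prcp, deg C for tmax/tmin, W/m2 for srad,
# degree-days for gdd.  Deterministic, so the conditional mean of yield can be
# recovered from a stored panel without re-simulating anomalies.
WEATHER_CLIMATOLOGY: dict[str, tuple[float, float, float, float]] = {
    "prcp": (2.8, 1.2, 28.0, 0.0),
    "tmax": (16.0, 14.0, 29.0, -np.inf),
    "tmin": (5.0, 13.0, 29.0, -np.inf),
    "srad": (180.0, 90.0, 26.0, 0.0),
    "gdd": (60.0, 60.0, 29.0, 0.0),
}
#: AR(1) anomaly parameters per variable: (autocorrelation, innovation sd).
WEATHER_AR1: dict[str, tuple[float, float]] = {
    "prcp": (0.55, 0.9),
    "tmax": (0.70, 1.8),
    "tmin": (0.70, 1.6),
    "srad": (0.60, 18.0),
    "gdd": (0.70, 9.0),
}
#: Per-soil-variable (county-level mean, between-county sd, depth gradient).
SOIL_BASES: dict[str, tuple[float, float, float]] = {
    "bulk_wet": (1.45, 0.10, 0.02),
    "bulk_dry": (1.30, 0.10, 0.02),
    "clay": (24.0, 6.0, 0.5),
    "paw": (0.18, 0.03, -0.002),
    "paw_ll": (0.10, 0.02, -0.001),
    "ksat": (28.0, 9.0, -1.0),
    "om": (3.0, 1.0, -0.15),
    "ph": (6.5, 0.5, 0.05),
    "sand": (30.0, 9.0, 0.4),
    "sat_wc": (0.45, 0.05, -0.003),
}


def climatology(var: str, weeks: np.ndarray) -> np.ndarray:
    """Deterministic weekly seasonal mean for one weather variable."""
    mean, amp, phase, floor = WEATHER_CLIMATOLOGY[var]
    vals = mean + amp * np.cos(2.0 * np.pi * (weeks - phase) / N_WEEKS)
    return np.maximum(vals, floor)


@dataclass(frozen=True)
class PanelSchema:
    """Dimensions and variable rosters of a generated panel."""

    n_states: int = 4
    counties_per_state: int = 10
    years: tuple[int, int] = (2000, 2019)
    n_weeks: int = N_WEEKS
    weather_vars: tuple[str, ...] = WEATHER_VARS
    soil_vars: tuple[str, ...] = SOIL_VARS
    n_soil_depths: int = N_SOIL_DEPTHS

    def __post_init__(self) -> None:
        if self.n_states < 1 or self.counties_per_state < 1 or self.n_weeks < 1:
            raise SchemaError("schema dimensions must be positive")
        if len(self.weather_vars) != 5:
            raise SchemaError("expected exactly 5 weather variables")
        if len(self.soil_vars) != 10 or self.n_soil_depths != 10:
            raise SchemaError("expected 10 soil variables at 10 depths")
        if self.year_span < 3:
            raise ValueError("years must span at least 3 so a trend can be fitted")

    @property
    def year_span(self) -> int:
        return self.years[1] - self.years[0] + 1

    @property
    def n_counties(self) -> int:
        return self.n_states * self.counties_per_state

    @property
    def n_records(self) -> int:
        return self.n_counties * self.year_span

    def state_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_states)]

    def county_names(self) -> list[str]:
        return [f"C{i + 1:03d}" for i in range(self.counties_per_state)]


@dataclass
class GenerativeTruth:
    """Materialized parameters of the data-generating process.

    Per-county arrays are ordered by (state index, county index); scalars and
    coefficient vectors are shared.  Units: yields in bu/acre, slopes in
    bu/acre per year; weather coefficients act on the season-mean anomaly of
    each variable (stored value minus deterministic climatology); soil
    coefficients act on standardized depth-mean soil scores.
    """

    intercepts: np.ndarray
    slopes: np.ndarray
    weather_coefs: np.ndarray
    soil_coefs: np.ndarray
    soil_quad: float
    noise_sd: float
    low_yield_fraction: float = 0.0
    schema: PanelSchema = field(default_factory=PanelSchema)

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.weather_coefs = np.asarray(self.weather_coefs, dtype=float)
        self.soil_coefs = np.asarray(self.soil_coefs, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n = self.schema.n_counties
        if self.intercepts.shape != (n,) or self.slopes.shape != (n,):
            raise ValueError(f"per-county arrays must have shape ({n},)")
        if self.weather_coefs.shape != (len(self.schema.weather_vars),):
            raise ValueError("one weather coefficient per weather variable")
        if self.soil_coefs.shape != (len(self.schema.soil_vars),):
            raise ValueError("one soil coefficient per soil variable")

    @classmethod
    def default(
        cls,
        schema: PanelSchema | None = None,
        seed: int = 0,
        noise_sd: float = 8.0,
        low_yield_fraction: float = 0.0,
    ) -> "GenerativeTruth":
        """Draw a realistic truth: ~150 bu/acre county means, ~1.8 bu/acre/yr
        technology trend, weather and soil effects of a few bu/acre each."""
        schema = schema or PanelSchema()
        rng = np.random.default_rng(seed)
        n = schema.n_counties
        return cls(
            intercepts=rng.normal(150.0, 12.0, size=n),
            slopes=rng.normal(1.8, 0.35, size=n),
            weather_coefs=np.array([9.0, -5.0, 3.5, 0.25, 0.45]),
            soil_coefs=rng.normal(0.0, 2.0, size=len(schema.soil_vars)),
            soil_quad=-3.0,
            noise_sd=noise_sd,
            low_yield_fraction=low_yield_fraction,
            schema=schema,
        )


def _county_index(df: pd.DataFrame, schema: PanelSchema) -> np.ndarray:
    states = {s: i for i, s in enumerate(schema.state_names())}
    counties = {c: i for i, c in enumerate(schema.county_names())}
    try:
        si = df["state"].map(states).to_numpy()
        ci = df["county"].map(counties).to_numpy()
    except KeyError as exc:  # pragma: no cover - guarded by FeaturePanel
        raise SchemaError(f"panel lacks key column {exc}") from exc
    if np.any(pd.isna(si)) or np.any(pd.isna(ci)):
        raise ValueError("panel contains locations unknown to this truth")
    return (si * schema.counties_per_state + ci).astype(int)


def _conditional_mean(df: pd.DataFrame, truth: GenerativeTruth) -> np.ndarray:
    """Noise-free mean yield per record, computed from stored panel columns."""
    schema = truth.schema
    weeks = np.arange(1, schema.n_weeks + 1)
    idx = _county_index(df, schema)
    y0 = schema.years[0]
    out = truth.intercepts[idx] + truth.slopes[idx] * (df["year"].to_numpy() - y0)

    for coef, var in zip(truth.weather_coefs, schema.weather_vars):
        cols = [weather_col(var, w) for w in weeks]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"weather block incomplete for {var}: missing {missing[:3]}")
        anom = df[cols].to_numpy().mean(axis=1) - climatology(var, weeks).mean()
        out = out + coef * anom

    z_scores = []
    for k, var in enumerate(schema.soil_vars):
        cols = [soil_col(var, d) for d in range(1, schema.n_soil_depths + 1)]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"soil block incomplete for {var}: missing {missing[:3]}")
        mean0, sd, grad = SOIL_BASES[var]
        depth_mean_clim = mean0 + grad * (np.arange(schema.n_soil_depths).mean())
        z = (df[cols].to_numpy().mean(axis=1) - depth_mean_clim) / sd
        z_scores.append(z)
        out = out + truth.soil_coefs[k] * z
    out = out + truth.soil_quad * (z_scores[0] ** 2 - 1.0)
    return out


def generate_panel(
    schema: PanelSchema, truth: GenerativeTruth, seed: int
) -> FeaturePanel:
    """Generate one complete county-year panel.

    The same (schema, truth, seed) triple always yields a bit-identical
    panel.  Yield = per-county trend + linear weather-anomaly effect +
    quadratic soil effect + N(0, noise_sd) noise, in bu/acre.
    """
    if truth.schema != schema:
        raise ValueError("truth was materialized for a different schema")
    rng = np.random.default_rng(seed)
    weeks = np.arange(1, schema.n_weeks + 1)
    years = np.arange(schema.years[0], schema.years[1] + 1)
    states, counties = schema.state_names(), schema.county_names()

    # State-year planting progress: logistic cumulative curves.
    progress: dict[tuple[str, int], np.ndarray] = {}
    for s in states:
        for y in years:
            mid = rng.normal(18.0, 1.5)
            width = rng.uniform(1.8, 3.0)
            curve = 100.0 / (1.0 + np.exp(-(weeks - mid) / width))
            progress[(s, y)] = np.clip(curve, 0.0, 100.0)

    # Static soil profiles per county.
    soil_rows: dict[tuple[str, str], np.ndarray] = {}
    depths = np.arange(schema.n_soil_depths)
    for s in states:
        for c in counties:
            prof = []
            for var in schema.soil_vars:
                mean0, sd, grad = SOIL_BASES[var]
                base = rng.normal(mean0, sd)
                prof.append(base + grad * depths + rng.normal(0.0, 0.05 * sd, size=depths.size))
            soil_rows[(s, c)] = np.concatenate(prof)

    key_rows = [(s, c, y) for s in states for c in counties for y in years]
    n_rec = len(key_rows)
    cols: dict[str, object] = {
        "state": [r[0] for r in key_rows],
        "county": [r[1] for r in key_rows],
        "year": [r[2] for r in key_rows],
    }
    pp = np.vstack([progress[(s, y)] for s, _, y in key_rows])
    for j, w in enumerate(weeks):
        cols[progress_col(w)] = pp[:, j]
    # weather: one bulk AR(1) pass per variable (x_t = phi x_{t-1} + eps_t)
    from scipy.signal import lfilter

    for var in schema.weather_vars:
        phi, innov = WEATHER_AR1[var]
        _, _, _, floor = WEATHER_CLIMATOLOGY[var]
        eps = rng.normal(0.0, innov, size=(n_rec, schema.n_weeks))
        anom = lfilter([1.0], [1.0, -phi], eps, axis=1)
        values = np.maximum(climatology(var, weeks)[None, :] + anom, floor)
        for j, w in enumerate(weeks):
            cols[weather_col(var, w)] = values[:, j]
    sx = np.vstack([soil_rows[(s, c)] for s, c, _ in key_rows])
    j = 0
    for var in schema.soil_vars:
        for d in range(1, schema.n_soil_depths + 1):
            cols[soil_col(var, d)] = sx[:, j]
            j += 1
    df = pd.DataFrame(cols)

    mean_yield = _conditional_mean(df, truth)
    noise = rng.normal(0.0, truth.noise_sd, size=len(df)) if truth.noise_sd > 0 else 0.0
    yields = mean_yield + noise
    if truth.low_yield_fraction > 0:
        n_low = int(round(truth.low_yield_fraction * len(df)))
        if n_low:
            pick = rng.choice(len(df), size=n_low, replace=False)
            yields[pick] = rng.uniform(0.0, 10.0, size=n_low)
    df["yield"] = yields  # target last, after all feature blocks
    return FeaturePanel(df, yield_unit="bu/acre", weather_vars=schema.weather_vars, soil_vars=schema.soil_vars)


def true_predictions(panel: FeaturePanel, truth: GenerativeTruth) -> np.ndarray:
    """Noise-free conditional mean yield for every record of *panel*.

    Serves as the oracle in model-recovery tests; raises :class:`SchemaError`
    if the panel lacks the weather or soil columns the truth references.
    """
    return _conditional_mean(panel.df, truth)
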