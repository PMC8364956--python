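"""Leave-future-year-out evaluation and metric conventions.

Metrics follow the usual yield-forecasting conventions: RMSE in the yield
unit, relative RMSE as a percentage of the mean observed yield, and R² as
the coefficient of determination (1 − SSE/SST about the observed mean),
which may be negative for a model worse than the mean predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import FeaturePanel


@dataclass
class MetricReport:
    group: str
    n: int
    rmse: float
    rrmse: float | None
    r2: float | None

    def as_dict(self) -> dict:
        return {"group": self.group, "n": self.n, "rmse": self.rmse, "rrmse": self.rrmse, "r2": self.r2}


def year_forward_split(
    panel: FeaturePanel, test_year: int, min_history: int = 3
) -> tuple[FeaturePanel, FeaturePanel]:
    """Train on every year strictly before *test_year*, test on it alone."""
    years = panel.df["year"]
    if test_year not in set(years):
        raise ValueError(f"test year {test_year} not present in panel")
    n_prior = len({y for y in years.unique() if y < test_year})
    if n_prior < min_history:
        raise ValueError(
            f"only {n_prior} years precede {test_year}; need >= {min_history}"
        )
    train = panel.copy(df=panel.df[years < test_year].reset_index(drop=True))
    test = panel.copy(df=panel.df[years == test_year].reset_index(drop=True))
    return train, test


def compute_metrics(
    predicted, observed, group: str = "overall"
) -> MetricReport:
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("predicted and observed must be equal-length, non-empty")
    resid = predicted - observed
    rmse = float(np.sqrt(np.mean(resid**2)))
    mean_obs = float(np.mean(observed))
    rrmse = 100.0 * rmse / mean_obs if mean_obs > 0 else None
    sst = float(np.sum((observed - mean_obs) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else None
    return MetricReport(group, predicted.size, rmse, rrmse, r2)


def per_group_metrics(
    table: pd.DataFrame,
    group_by: str,
    predicted_col: str = "predicted",
    observed_col: str = "observed",
) -> list[MetricReport]:
    """One report per group plus the pooled "overall" report.

    *table* must carry the grouping key column plus predicted/observed.
    """
    if group_by not in ("state", "year", "county"):
        raise ValueError(f"unknown grouping {group_by!r}")
    if group_by not in table.columns:
        raise ValueError(f"table lacks column {group_by!r}")
    reports = [
        compute_metrics(grp[predicted_col], grp[observed_col], group=str(key))
        for key, grp in table.groupby(group_by, sort=True)
    ]
    reports.append(compute_metrics(table[predicted_col], table[observed_col]))
    return reports


def relative_error_map_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per county-year signed relative error, in percent of that year's mean
    observed yield: 100·(predicted − observed)/mean(observed in year)."""
    out = []
    for year, grp in table.groupby("year", sort=True):
        mean_obs = grp["observed"].mean()
        if not mean_obs > 0:
            import warnings

            warnings.warn(f"year {year}: non-positive mean observed yield; skipped")
            continue
        g = grp[["state", "county", "year"]].copy()
        g["relative_error_pct"] = 100.0 * (grp["predicted"] - grp["observed"]) / mean_obs
        out.append(g)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["state", "county", "year", "relative_error_pct"]
    )


def reports_to_frame(reports: list[MetricReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])
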