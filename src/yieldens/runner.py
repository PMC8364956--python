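"""Configuration-driven orchestration of a full experiment.

Stage order is fixed: data (generate or load) → year-forward split →
preprocessing (fitted on training years only) → stratified 20% validation
holdout → base-model roster(s) → combiners fitted on the holdout OOB matrix
→ test-year evaluation.  Every stage draws its randomness from the single
run seed, so identical configs reproduce identical artifacts bit-for-bit.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensembles as ens
from .evaluation import compute_metrics, reports_to_frame, year_forward_split
from .network import NetworkSpec
from .panel import FeaturePanel
from .preprocess import DEFAULT_SEASON, assemble_feature_blocks, preprocess_train_test
from .synthetic import GenerativeTruth, PanelSchema, generate_panel


class ConfigError(ValueError):
    """The run configuration is inconsistent or incomplete."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment."""

    # exactly one data source
    synthetic: dict | None = None  # PanelSchema/truth keyword arguments
    panel_csv: str | None = None

    test_year: int = 2019
    season: tuple[int, int] = DEFAULT_SEASON
    n_periods: int = 4

    scenarios: list[dict] = field(
        default_factory=lambda: [{"name": "homogeneous", "k": 10}]
    )
    combiners: list[str] = field(default_factory=lambda: ["bem", "gem", "stacked:ols"])
    spec: dict = field(default_factory=dict)  # NetworkSpec overrides
    reduced_scale: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.panel_csv is None):
            raise ConfigError("exactly one of synthetic/panel_csv must be set")
        for c in self.combiners:
            kind = c.split(":", 1)
            if kind[0] not in ("bem", "gem", "stacked"):
                raise ConfigError(f"unknown combiner {c!r}")
            if kind[0] == "stacked" and (
                len(kind) != 2 or kind[1] not in ens.STACKED_KINDS
            ):
                raise ConfigError(f"stacked combiner needs a learner kind: {c!r}")
        for sc in self.scenarios:
            if sc.get("name") not in ("homogeneous", "heterogeneous"):
                raise ConfigError(f"unknown scenario {sc!r}")
        self.season = tuple(self.season)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def base_spec(self) -> NetworkSpec:
        spec = NetworkSpec(seed=self.seed)
        if self.reduced_scale:
            spec = spec.reduced()
        if self.spec:
            from dataclasses import asdict

            d = asdict(spec)
            unknown = set(self.spec) - set(d)
            if unknown:
                raise ConfigError(f"unknown spec overrides: {sorted(unknown)}")
            d.update(self.spec)
            for k in ("weather_kernels", "soil_kernels", "weather_pools", "soil_pools", "fc1", "fc2"):
                d[k] = tuple(d[k])
            spec = NetworkSpec(**d)
        return spec


def load_panel(config: RunConfig) -> FeaturePanel:
    if config.panel_csv is not None:
        return FeaturePanel.from_csv(config.panel_csv)
    kw = dict(config.synthetic or {})
    truth_seed = kw.pop("truth_seed", config.seed)
    panel_seed = kw.pop("panel_seed", config.seed + 1)
    noise_sd = kw.pop("noise_sd", 8.0)
    low_frac = kw.pop("low_yield_fraction", 0.0)
    if "years" in kw:
        kw["years"] = tuple(kw["years"])
    schema = PanelSchema(**kw)
    truth = GenerativeTruth.default(
        schema, seed=truth_seed, noise_sd=noise_sd, low_yield_fraction=low_frac
    )
    return generate_panel(schema, truth, seed=panel_seed)


def _fit_roster(config, scenario, train_proc, split, spec):
    if scenario["name"] == "homogeneous":
        k = int(scenario.get("k", 10))
        return ens.fit_homogeneous_bases(train_proc, spec, k=k, split=split, seed=config.seed)
    counts = scenario.get("filter_counts", (2, 3, 4, 5, 6))
    specs = ens.heterogeneous_specs(counts, template=spec)
    return ens.fit_heterogeneous_bases(train_proc, specs, split=split, seed=config.seed)


def _fit_combiner(name: str, oob, roster, seed: int):
    if name == "bem":
        return ens.fit_bem(oob, roster)
    if name == "gem":
        return ens.fit_gem(oob, roster)
    _, learner_kind = name.split(":", 1)
    return ens.fit_stacked_learner(oob, learner_kind, roster, seed=seed)


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns (and optionally writes) a manifest
    with metric reports, OOB matrices, weights and all seeds.

    On a stage failure the partial manifest collected so far is attached to
    the raised exception as ``exc.partial_manifest``.
    """
    manifest: dict = {"config": _config_dict(config), "stages": []}
    t0 = time.time()
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    try:
        panel = load_panel(config)
        _stage(manifest, "data", t0, records=len(panel))

        train_raw, test_raw = year_forward_split(panel, config.test_year)
        _stage(manifest, "split", t0, train=len(train_raw), test=len(test_raw))

        train_proc, test_proc, fitted = preprocess_train_test(
            train_raw, test_raw, season_weeks=config.season, n_periods=config.n_periods
        )
        manifest["preprocess"] = fitted.metadata_lines()
        _stage(manifest, "preprocess", t0, train=len(train_proc), test=len(test_proc))

        split = ens.stratified_holdout_split(train_proc, seed=config.seed)
        manifest["split_plan"] = {
            "seed": split.seed,
            "bin_edges": [float(e) for e in split.bin_edges],
            "n_train": int(split.train_idx.size),
            "n_val": int(split.val_idx.size),
        }

        spec = config.base_spec()
        test_blocks = assemble_feature_blocks(test_proc)
        observed = test_blocks.y

        # trend-only baseline: the extrapolated per-location OLS line
        trend_pred = np.array(
            [
                fitted.trend_models[(s, c)].predict(y)
                for s, c, y in zip(
                    test_proc.df["state"], test_proc.df["county"], test_proc.df["year"]
                )
            ]
        )
        baseline = compute_metrics(trend_pred, observed, group="trend_baseline")

        all_reports = []
        manifest["scenarios"] = {}
        for scenario in config.scenarios:
            name = scenario["name"]
            roster, oob = _fit_roster(config, scenario, train_proc, split, spec)
            _stage(manifest, f"bases:{name}", t0, k=len(roster))
            entry: dict = {
                "model_ids": oob.model_ids,
                "fingerprints": [b.data_fingerprint for b in roster],
            }
            if out_dir is not None:
                oob.to_frame().to_csv(Path(out_dir) / f"oob_{name}.csv", index=False)
            for comb in config.combiners:
                model = _fit_combiner(comb, oob, roster, seed=config.seed)
                if model.kind == "gem":
                    entry["gem_weights"] = [float(x) for x in model.weights.w]
                pred = ens.predict_ensemble(model, test_blocks)
                rep = compute_metrics(pred, observed, group=f"{name}:{comb}")
                all_reports.append(rep)
            manifest["scenarios"][name] = entry
            _stage(manifest, f"combine:{name}", t0)

        all_reports.append(baseline)
        reports = reports_to_frame(all_reports)
        manifest["metrics"] = reports.to_dict(orient="records")
        manifest["elapsed_s"] = round(time.time() - t0, 2)
        if out_dir is not None:
            out = Path(out_dir)
            reports.to_csv(out / "metrics.csv", index=False)
            with open(out / "manifest.yaml", "w") as fh:
                yaml.safe_dump(manifest, fh, sort_keys=True)
        return manifest
    except Exception as exc:
        exc.partial_manifest = manifest  # type: ignore[attr-defined]
        raise


def _stage(manifest, name, t0, **info):
    manifest["stages"].append(
        {"stage": name, "t_s": round(time.time() - t0, 2), **info}
    )


def _config_dict(config: RunConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    d["season"] = list(d["season"])
    return d
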