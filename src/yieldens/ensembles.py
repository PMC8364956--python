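"""Base-model roster generation and ensemble combination.

Two roster scenarios:

* homogeneous — one network specification, k bootstrap resamples of the
  training records, one model per resample (bagging);
* heterogeneous — k specifications differing in conv filter count, all
  trained on the same training records.

Either roster predicts a stratified 20% validation holdout; that prediction
matrix (the "out-of-bag" matrix) is the only input to the combiners:

* BEM — unweighted average of base predictions;
* GEM — convex weights minimizing validation MSE over the probability
  simplex (a quadratic program, solved with SLSQP);
* stacked generalization — a second-level learner (OLS, LASSO, random
  forest or gradient-boosted trees) fitted on base predictions vs truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .panel import FeaturePanel
from .preprocess import FeatureBlocks, assemble_feature_blocks
from .network import NetworkSpec, TrainedBase, build_base_network, predict_yields, train_network

STACKED_KINDS = ("ols", "l1-linear", "random-forest", "gradient-boosted-trees")


# ---------------------------------------------------------------------------
# stratified holdout split
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Index-level partition of a training panel into train and validation.

    Records are binned into ``n_bins`` linearly spaced yield intervals and a
    fixed fraction of each bin is drawn (without replacement) into the
    validation set, so validation mirrors the training yield distribution.
    """

    train_idx: np.ndarray
    val_idx: np.ndarray
    bin_edges: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.val_idx).size:
            raise ValueError("train and validation indices overlap")


def stratified_holdout_split(
    train_panel: FeaturePanel,
    fraction: float = 0.2,
    n_bins: int = 5,
    seed: int = 0,
) -> SplitPlan:
    if len(train_panel) == 0:
        raise ValueError("training panel is empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    y = train_panel.df["yield"].to_numpy(dtype=float)
    edges = np.linspace(y.min(), y.max(), n_bins + 1)
    # right-inclusive top bin so the maximum is not orphaned
    bins = np.clip(np.digitize(y, edges[1:-1]), 0, n_bins - 1)
    rng = np.random.default_rng(seed)
    val: list[np.ndarray] = []
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        if members.size < 2:
            if members.size:
                warnings.warn(
                    f"yield bin {b} has {members.size} record(s); kept in training"
                )
            continue
        n_val = int(round(fraction * members.size))
        if n_val:
            val.append(rng.choice(members, size=n_val, replace=False))
    val_idx = np.sort(np.concatenate(val)) if val else np.array([], dtype=int)
    train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
    return SplitPlan(train_idx, val_idx, edges, seed)


def bootstrap_resample(train_keys: np.ndarray, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Draw *k* bootstrap multisets (with replacement, same cardinality)."""
    train_keys = np.asarray(train_keys)
    if train_keys.size == 0:
        raise ValueError("cannot bootstrap an empty key set")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    return [rng.choice(train_keys, size=train_keys.size, replace=True) for _ in range(k)]


# ---------------------------------------------------------------------------
# OOB matrix and roster fitting
# ---------------------------------------------------------------------------

@dataclass
class OOBMatrix:
    """Validation-holdout prediction matrix: column j = base model j."""

    P: np.ndarray  # (n_val, k)
    y: np.ndarray  # (n_val,)
    model_ids: list[str]
    keys: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.y.size:
            raise ValueError("P must be (n_val, k) aligned with y")
        if not np.all(np.isfinite(self.P)):
            raise ValueError("OOB matrix contains non-finite entries")

    @property
    def k(self) -> int:
        return self.P.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.P, columns=self.model_ids)
        df["yield_true"] = self.y
        if self.keys is not None:
            df = pd.concat([self.keys.reset_index(drop=True), df], axis=1)
        return df


def _train_one(spec: NetworkSpec, blocks: FeatureBlocks, seed: int) -> TrainedBase:
    model = build_base_network(
        spec,
        weather_length=blocks.weather.shape[2],
        n_other=blocks.other.shape[1],
        n_weather_vars=blocks.weather.shape[1],
        n_soil_vars=blocks.soil.shape[1],
        soil_depths=blocks.soil.shape[2],
    )
    return train_network(model, blocks, spec, seed=seed)


def fit_homogeneous_bases(
    train_panel: FeaturePanel,
    spec: NetworkSpec,
    k: int = 10,
    split: SplitPlan | None = None,
    seed: int = 0,
) -> tuple[list[TrainedBase], OOBMatrix]:
    """Bagging: k bootstrap resamples of the split's training records, one
    model per resample; every model predicts the untouched validation set."""
    if split is None:
        split = stratified_holdout_split(train_panel, seed=seed)
    blocks = assemble_feature_blocks(train_panel)
    val_blocks = blocks.take(split.val_idx)
    replicates = bootstrap_resample(split.train_idx, k=k, seed=seed)
    roster, cols = [], []
    for j, rep in enumerate(replicates):
        base_spec = NetworkSpec(**{**_spec_dict(spec), "seed": spec.seed + j})
        try:
            base = _train_one(base_spec, blocks.take(rep), seed=seed + 1000 + j)
        except Exception as exc:
            raise RuntimeError(f"training failed for bootstrap replicate {j}") from exc
        roster.append(base)
        cols.append(predict_yields(base, val_blocks))
    oob = OOBMatrix(
        np.column_stack(cols),
        val_blocks.y,
        [f"bag{j:02d}" for j in range(k)],
        keys=train_panel.keys().iloc[split.val_idx],
    )
    return roster, oob


def fit_heterogeneous_bases(
    train_panel: FeaturePanel,
    specs: list[NetworkSpec],
    split: SplitPlan | None = None,
    seed: int = 0,
    ids: list[str] | None = None,
) -> tuple[list[TrainedBase], OOBMatrix]:
    """Filter-count variants: every spec is trained on the same training
    records (no resampling); OOB columns follow the spec order.

    Each model's training randomness derives from (run seed, spec seed), so
    two entries with fully identical specs yield identical columns — zero
    diversity, but a well-defined edge case.
    """
    if ids is None:
        ids = [f"m{j:02d}_nf{s.n_filters}" for j, s in enumerate(specs)]
    if len(ids) != len(specs):
        raise ValueError("one identifier per spec required")
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate spec identifiers: {ids}")
    if split is None:
        split = stratified_holdout_split(train_panel, seed=seed)
    blocks = assemble_feature_blocks(train_panel)
    train_blocks = blocks.take(split.train_idx)
    val_blocks = blocks.take(split.val_idx)
    roster, cols = [], []
    for spec in specs:
        base = _train_one(spec, train_blocks, seed=seed + 2000 + spec.seed)
        roster.append(base)
        cols.append(predict_yields(base, val_blocks))
    oob = OOBMatrix(
        np.column_stack(cols), val_blocks.y, ids,
        keys=train_panel.keys().iloc[split.val_idx],
    )
    return roster, oob


def _spec_dict(spec: NetworkSpec) -> dict:
    from dataclasses import asdict

    return asdict(spec)


def heterogeneous_specs(
    filter_counts=(2, 3, 4, 5, 6), template: NetworkSpec | None = None
) -> list[NetworkSpec]:
    """The standard heterogeneous roster: same architecture, conv filter
    counts varied (2–6 by default)."""
    template = template or NetworkSpec()
    return [
        NetworkSpec(**{**_spec_dict(template), "n_filters": nf, "seed": template.seed + i})
        for i, nf in enumerate(filter_counts)
    ]


# ---------------------------------------------------------------------------
# combiners
# ---------------------------------------------------------------------------

@dataclass
class EnsembleWeights:
    """Convex combination weights over a base roster (simplex point)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < -1e-12):
            raise ValueError("weights must be nonnegative")
        self.w = np.clip(self.w, 0.0, None)
        s = self.w.sum()
        if abs(s - 1.0) > 1e-8:
            raise ValueError(f"weights must sum to 1 (got {s})")
        self.w = self.w / s


def combine_bem(P: np.ndarray) -> np.ndarray:
    """Basic ensemble: row-wise arithmetic mean of base predictions."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] < 1:
        raise ValueError("P must be a 2-D matrix with at least one column")
    return P.mean(axis=1)


def gem_objective(w: np.ndarray, P: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error of the w-weighted combination."""
    r = P @ w - y
    return float(np.mean(r * r))


def fit_gem_weights(oob: OOBMatrix) -> EnsembleWeights:
    """Minimize validation MSE over the probability simplex.

    The objective (1/n)·Σ_i (y_i − Σ_j w_j ŷ_ij)² is a convex quadratic;
    SLSQP starts at equal weights and the equal-weight solution is kept as a
    guaranteed-feasible fallback, so the returned objective never exceeds the
    plain average's.
    """
    P, y, k = oob.P, oob.y, oob.k
    if k == 1:
        return EnsembleWeights(np.ones(1))
    w0 = np.full(k, 1.0 / k)

    def grad(w, P, y):
        return 2.0 / len(y) * P.T @ (P @ w - y)

    res = minimize(
        gem_objective,
        w0,
        args=(P, y),
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(k)}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None)
    s = w.sum()
    if s <= 0 or not np.all(np.isfinite(w)):
        w, s = w0, 1.0
    w = w / s
    if gem_objective(w, P, y) > gem_objective(w0, P, y):
        w = w0
    if not res.success and gem_objective(w, P, y) > gem_objective(w0, P, y) + 1e-10:
        raise RuntimeError(
            f"GEM solver did not converge: best objective {gem_objective(w, P, y)}"
        )
    return EnsembleWeights(w)


def apply_weights(w: EnsembleWeights, P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.shape[1] != w.w.size:
        raise ValueError(f"P has {P.shape[1]} columns but weights have {w.w.size}")
    return P @ w.w


def _make_learner(kind: str, seed: int = 0):
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.linear_model import Lasso, LinearRegression

    if kind == "ols":
        return LinearRegression()
    if kind == "l1-linear":
        return Lasso(alpha=1.0, max_iter=50_000)
    if kind == "random-forest":
        return RandomForestRegressor(n_estimators=200, random_state=seed)
    if kind == "gradient-boosted-trees":
        import lightgbm

        return lightgbm.LGBMRegressor(
            n_estimators=200, random_state=seed, verbose=-1, deterministic=True,
            force_row_wise=True,
        )
    raise ValueError(f"unknown learner kind {kind!r}; choose from {STACKED_KINDS}")


@dataclass
class EnsembleModel:
    """A fitted combiner over a fixed roster of trained base models."""

    kind: str  # "bem" | "gem" | "stacked"
    roster: list[TrainedBase] = field(default_factory=list)
    weights: EnsembleWeights | None = None
    learner: object | None = None
    learner_kind: str | None = None

    def combine(self, P: np.ndarray) -> np.ndarray:
        if self.kind == "bem":
            return combine_bem(P)
        if self.kind == "gem":
            if self.weights is None:
                raise ValueError("GEM model has no fitted weights")
            return apply_weights(self.weights, P)
        if self.kind == "stacked":
            if self.learner is None:
                raise ValueError("stacked model has no fitted learner")
            return np.asarray(self.learner.predict(np.asarray(P, dtype=float)))
        raise ValueError(f"unknown ensemble kind {self.kind!r}")

    def predict(self, blocks: FeatureBlocks) -> np.ndarray:
        if not self.roster:
            raise ValueError("ensemble has no base roster attached")
        P = np.column_stack([predict_yields(b, blocks) for b in self.roster])
        return self.combine(P)


def fit_bem(oob: OOBMatrix, roster: list[TrainedBase] | None = None) -> EnsembleModel:
    return EnsembleModel("bem", roster or [])


def fit_gem(oob: OOBMatrix, roster: list[TrainedBase] | None = None) -> EnsembleModel:
    return EnsembleModel("gem", roster or [], weights=fit_gem_weights(oob))


def fit_stacked_learner(
    oob: OOBMatrix, learner_kind: str, roster: list[TrainedBase] | None = None, seed: int = 0
) -> EnsembleModel:
    """Fit a second-level learner on (base predictions → true yield).

    Base predictions are the only second-level features.
    """
    learner = _make_learner(learner_kind, seed=seed)
    learner.fit(oob.P, oob.y)
    return EnsembleModel("stacked", roster or [], learner=learner, learner_kind=learner_kind)


def predict_stacked(model: EnsembleModel, P: np.ndarray) -> np.ndarray:
    return model.combine(P)


def predict_ensemble(model: EnsembleModel, blocks: FeatureBlocks) -> np.ndarray:
    """End-to-end inference: roster predictions column-wise, then combine."""
    return model.predict(blocks)
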