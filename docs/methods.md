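# Methods

## Data model

A panel is one row per (state, county, year) with four feature blocks and a
yield target in bu/acre (62.77 kg/ha per bu/acre for 56 lb/bu corn):

* planting progress `pp_w01..pp_w52` — state-level cumulative % planted,
  non-decreasing over weeks, bounded in [0, 100];
* weather `<var>_w01..w52` for `prcp, tmax, tmin, srad, gdd` (260 columns
  raw); `gdd` is treated as an opaque accumulated thermal-time channel — no
  base temperature is assumed;
* soil `<var>_d01..d10` for ten properties at ten profile depths
  (100 columns), constant across years within a county;
* engineered: period aggregates `agg_*` and the `yield_trend` covariate.

## Preprocessing pipeline

Fixed order: impute → trim → aggregate → outlier-filter → trend → scale.
All fitted transforms see training years only.

* **Imputation** — a state with missing weekly progress takes the
  arithmetic mean of two donor states for the same week and year; only
  missing cells are touched.
* **Season trimming** — weather and progress columns outside the growing
  season are dropped. The window is configurable; the default is weeks
  14–45 inclusive, i.e. 32 retained weeks, which is exactly the input
  length of each weather conv branch. (The architecture fixes the input
  length; the calendar window itself is not canonical, and 14–45 spans
  typical Corn Belt planting through harvest.)
* **Aggregation** — per period (default: the trimmed season split into 4
  near-equal "quarters"; boundaries are not canonical and are
  configurable) and per whole season: precipitation and radiation are
  summed, temperatures and gdd averaged. Weekly columns are retained and
  feed the CNN branches; the aggregates feed the flat-covariate branch.
* **Outlier rule** — records with yield strictly below 10 bu/acre are
  dropped (the boundary value survives). The rule is defined in bu/acre
  and refuses to run on converted targets.
* **Yield trend** — per location i, OLS of yield on calendar year:
  ŷ_i = b0_i + b1_i·YEAR, fitted on training years and extrapolated to
  test years. Locations with fewer than two training years get slope 0 and
  intercept equal to their mean yield (avoids a singular fit while keeping
  the feature defined). A test location without a fitted model is an
  error — the county roster is fixed across years, so this signals a split
  bug rather than data to impute. The same extrapolated line is also the
  "trend baseline" that ensembles are compared against.
* **Scaling** — min-max to [0, 1] per feature, bounds from training data
  only; constant features map to 0; test values are *not* clipped, so they
  may fall outside [0, 1]. This mirrors scikit-learn's min-max behaviour
  but is kept as a small serializable class because the bounds are written
  to a plain-text sidecar.

## Base network

Per weather variable, a 1-D conv chain on the 32 in-season weeks: kernels
(6, 3, 3), each followed by window-2 stride-2 average pooling, all
convolutions valid, ReLU activations; with NF filters per layer the length
arithmetic is 32→27→13→11→5→3→1, so each branch emits NF values. Per soil
variable, kernels (3, 3, 3) with pooling after the first two convolutions:
10→8→4→2→1. The third kernel-3 convolution cannot be applied to a
length-1 sequence under strict valid rules; the declared (configurable)
fallback left-pads with the edge value up to the kernel length, after which
the branch emits NF values. This reproduces the published per-branch
output size; the unavoidable ambiguity in how the original soil chain was
reconciled is noted here rather than guessed away.

Branch outputs are concatenated per group and aggregated: FC_W (60 units)
for the five weather branches, FC_S (40) for the ten soil branches; the
flat covariates (trimmed progress + aggregates + yield trend) pass through
FC1 (64, 32, 16). The concatenation (60+40+16 = 116) feeds FC2 (128, 64)
with dropout 0.5 after each hidden layer and a single linear output.

Training: Adam (lr 1e-4), batch 16, MSE loss, 1000 epochs at full scale;
dropout active only in training; He initialization with a recorded seed;
batches reshuffle every epoch with the run seed. Targets are standardized
internally (training mean/sd, inverted at prediction) so the optimizer's
step size is independent of the yield unit. Whether the original training
shuffled per epoch is unknown; seeded shuffling is used. The loss is MSE
(consistent with RMSE reporting and the squared-error ensemble objective).

**Desk scale.** `NetworkSpec.reduced()` keeps the architecture but adapts
the optimization to a 50-epoch budget: lr 2e-3 with cosine annealing to 0,
batch 8, dropout 0.2. The full-scale constant-1e-4/1000-epoch regime ends
with effectively tiny steps; annealing reproduces that settling behaviour
at short horizons, and lighter dropout matches the much smaller number of
updates. Constant-lr full-scale defaults are untouched.

The whole network is NumPy: forward, backward and Adam are hand-written,
and the test suite checks analytic gradients against central finite
differences (worst relative error ~1e-6 on off-kink parameters) and the
trainable-parameter count against an independent hand count.

## Ensembles

* **Holdout OOB predictions.** Cross-validation cannot give one consistent
  out-of-bag prediction vector when the training data is itself resampled
  per base model, so a single stratified 20% validation holdout is used
  instead: training yields are binned into 5 linearly spaced bins and 20%
  of each bin (rounded; bins with fewer than 2 records stay in training
  with a warning) is drawn without replacement. The holdout is shared by
  GEM and all stacked learners.
* **Homogeneous roster** — k bootstrap resamples (with replacement,
  county-year records as the resampling unit, same cardinality) of the
  80% training part; one model per resample, per-replicate seeds.
* **Heterogeneous roster** — k filter-count variants (default NF 2–6)
  trained on the same 80% without resampling. Per-model training seeds
  derive from the spec seed, so fully identical specs reproduce identical
  prediction columns.
* **BEM** — row-wise mean of the prediction matrix.
* **GEM** — the simplex QP above, solved by SLSQP from the equal-weight
  start; the equal-weight point is kept as a feasible fallback so the
  returned objective never exceeds BEM's; solver round-off below 0 is
  clipped and renormalized (threshold 1e-12). Correctness is checked
  against an exhaustive 0.01-step simplex grid oracle.
* **Stacking** — scikit-learn LinearRegression / Lasso / RandomForest and
  LightGBM heads fitted on (P → y) of the holdout; base predictions are
  the only second-level features by default.
* Test-time ensemble predictions reuse the bases as trained (no refit on
  train+validation); a refit variant is deliberately not the default, as
  the holdout protocol above is only coherent if the combiner's inputs
  come from models that never saw the holdout.

These choices imply, on the fitting holdout, MSE(stacked-OLS) ≤ MSE(GEM) ≤
MSE(BEM): equal weights are GEM-feasible, and every simplex point is
feasible for the unconstrained OLS head. The suite asserts this nesting
per instance.

## Evaluation

Leave-future-year-out: train on all years strictly before the test year
(at least 3 required), test on that year alone. RMSE in the yield unit;
RRMSE = 100·RMSE / mean(observed), reported only for positive mean; R² =
1 − SSE/SST about the observed test mean — a coefficient of determination,
not a squared correlation; negative values are reported as-is. Per-state /
per-year / per-county breakdowns aggregate back to the overall RMSE as the
record-weighted quadratic mean. A per-county signed relative error table
(100·(pred − obs)/year-mean observed) supports mapping over/under
prediction.

## Synthetic generator

What it emulates: the exact column schema above; per-county yield trends
(intercepts ~N(150, 12) bu/acre, slopes ~N(1.8, 0.35) bu/acre/yr); weekly
weather as a deterministic seasonal sinusoid per variable plus AR(1)
anomalies (autocorrelation 0.55–0.7), whose season-mean anomaly enters
yield linearly; static soil depth profiles whose standardized depth-means
enter linearly plus a quadratic term in the first property (so nonlinear
learners have something to gain); i.i.d. N(0, 8) bu/acre noise; logistic
state-level planting curves; optionally a small fraction of sub-10 bu/acre
records to exercise the outlier filter (default 0 — outliers deliberately
break the truth/yield correspondence the recovery tests rely on).

What it does not emulate: spatial correlation between neighbouring
counties, common year-wide weather shocks, irrigation, measurement error in
reported yields, or any real-world file format. Passing tests therefore
demonstrate that the machinery (preprocessing, training, combining,
evaluation) behaves as specified under the assumed structure — not that the
model attains any particular accuracy on real agency data.

## Numerical choices and degenerate inputs

* GEM ties between optimal vertices resolve by the deterministic
  equal-weight start; k = 1 short-circuits to weight 1.
* Min-max scaling of a constant feature yields 0; zero-variance observed
  vectors make R² undefined (reported missing); empty panels filter to
  empty panels.
* Average pooling floors odd lengths (the trailing element is dropped).
* Non-finite training loss raises immediately with the epoch and batch
  index; predictions are checked finite.
* All randomness flows from explicit integer seeds; reruns are
  bit-identical, which the suite and the acceptance script both verify.

## Scale of the shipped experiments

The bundled end-to-end experiment uses a 40-county × 20-year panel,
reduced 2-filter networks, 50 epochs, k = 4 bags and filter counts {2, 3} —
sizes chosen so the whole suite runs comfortably on a laptop-class single
CPU while still separating the ensembles from the trend baseline. The
full-scale configuration (NF = 4, k = 10, NF ∈ {2..6}, 1000 epochs) is the
package default for real panels.

## Known limitations

* The NumPy network is single-threaded and CPU-bound; it is meant for
  panels of 10³–10⁴ records, not for the ~40k-record scale of a full
  multi-decade 12-state panel.
* The soil conv-chain padding fallback is one defensible reading of an
  under-specified architecture detail; a different reconciliation would
  change parameter counts slightly.
* Stratified splitting guarantees the 20% fraction only up to per-bin
  rounding.
* LASSO and tree stacking heads inherit their libraries' own numerical
  behaviour (e.g. coordinate-descent convergence warnings at near-zero
  penalties).
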