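# yieldens

Ensemble CNN-DNN prediction of county-level crop yields from weather, soil
and management panels.

## The problem

County-level corn yield forecasting combines three very different kinds of
information: weekly in-season weather (five variables × 52 weeks), static
soil depth profiles (ten properties × ten depths), state-level weekly
planting progress, and a strong technological trend in historical yields.
`yieldens` implements a two-layer convolutional/fully-connected base
regressor for such county-year panels and, on top of it, the three classic
ways of combining a roster of fitted base models into an ensemble:

* **BEM** (basic ensemble method) — the unweighted average
  ŷ = (1/k) Σ_j ŷ_j;
* **GEM** (generalized ensemble method) — the convex combination
  ŷ = Σ_j w_j ŷ_j with weights solving

      min_w  (1/n) Σ_i ( y_i − Σ_j w_j ŷ_ij )²
      s.t.   Σ_j w_j = 1,  w_j ≥ 0,

  a quadratic program over the probability simplex, fitted on held-out
  validation predictions;
* **stacked generalization** — a second-level learner (OLS, LASSO, random
  forest or gradient-boosted trees) trained to map the k base predictions
  to the observed yield on the same holdout.

Rosters come in two flavours: **homogeneous** (one architecture, k bootstrap
resamples of the training records — bagging) and **heterogeneous** (k
architecture variants differing in the number of convolution filters, all
trained on the same data). Evaluation is leave-future-year-out: train on
all years before the test year, predict the test year, and report RMSE,
relative RMSE (100·RMSE / mean observed yield) and R².

The base network routes each weather variable and each soil variable
through its own small 1-D CNN (valid convolutions, stride-2 average
pooling), aggregates the branches with one-hidden-layer networks (60 and 40
units), passes the remaining covariates — planting progress, period weather
aggregates and a per-location OLS yield-trend feature — through a
three-layer network (64/32/16), and feeds the concatenation to a 128/64
head with dropout and a linear output. Training is Adam on mean squared
error. The network, including backpropagation, is implemented in NumPy
and verified against finite-difference gradients in the test suite.

Because the real USDA/NASA-Power/SSURGO panels are not redistributable, the
package ships a synthetic-data module that generates panels with the same
schema and the statistical structure the method assumes (per-county linear
yield trends, seasonal weather with AR(1) anomalies, static soil profiles
with a mildly nonlinear yield effect, Gaussian noise), along with the
generating truth so model-recovery tests have an oracle.

## Worked example

```bash
yieldens run-all --config examples/quickstart.yaml --out-dir out/
```

generates a 24-county × 15-year synthetic panel, holds out the final year,
trains a bagged roster (k=3) and a filter-count roster (2 and 3 filters) of
reduced base networks, combines each with BEM, GEM and stacked OLS, and
prints (about 30 s on one CPU):

```
         homogeneous:bem  n=  24  rmse=14.68  rrmse=8.59%  r2=-0.264
         homogeneous:gem  n=  24  rmse=14.66  rrmse=8.58%  r2=-0.261
 homogeneous:stacked:ols  n=  24  rmse=14.59  rrmse=8.54%  r2=-0.249
       heterogeneous:bem  n=  24  rmse=13.98  rrmse=8.18%  r2=-0.147
       heterogeneous:gem  n=  24  rmse=13.99  rrmse=8.18%  r2=-0.147
heterogeneous:stacked:ols  n=  24  rmse=13.64  rrmse=7.98%  r2=-0.091
          trend_baseline  n=  24  rmse=14.95  rrmse=8.74%  r2=-0.310
```

RMSE is in bu/acre (the panel's native unit); `rrmse` is the percentage of
the mean observed test yield; `r2` is the coefficient of determination on
the test year. Every ensemble predicts the held-out year better than the
`trend_baseline`, which extrapolates each county's fitted yield-on-year OLS
line — the bar any weather-aware model has to clear. On this deliberately
small run all R² values are negative (the single test year's yields sit
close to their mean, so beating the test-set mean predictor is hard); the
ordering between models, not the absolute R², is the point of the example.
The output directory holds `manifest.yaml` (seeds, split, GEM weights),
`oob_*.csv` (validation prediction matrices) and `metrics.csv`.

The same stages are available individually (`yieldens simulate`,
`preprocess`, `train-bases`, `combine`, `evaluate`) and as library
functions; see `docs/methods.md` for the modelling details.

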