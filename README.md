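# cropfda

Varying-coefficient functional regression for year-round greenhouse crop
yields.

In long-term protected cultivation (strawberry, high-wire tomato), daily
yield responds to the environmental history of the preceding weeks, and the
shape of that response drifts with the season: warmth six weeks before a
March harvest helps a strawberry crop, the same warmth before a May harvest
hurts it.  `cropfda` models this with a scalar-on-function regression whose
coefficient is a *surface* over lag and season,

```
y_i(t_i) = α(t_i) + Σ_{j=1..J} ∫₀ᴸ x_ij(s) β_j(s, t_i) ds + ε_i
```

where `y_i` is the 7-day forward moving average of daily yield at harvest
date with day-of-season `t_i`; `x_ij(s)` is the j-th environmental factor
(temperature, solar radiation) `s` days before harvest, observed over a lag
window of `L` = 60 days (strawberry) or 80 days (tomato), hourly-averaged and
expressed in a cubic B-spline basis; `β_j(s,t)` is a tensor-product B-spline
surface estimated by penalized least squares with separate roughness
penalties `λ_s ∬ (∂²β/∂s²)²` and `λ_t ∬ (∂²β/∂t²)²`; and `α(t)` is a smooth
seasonal intercept (see `docs/methods.md`).  Setting the surface constant in
`t` recovers the classical functional regression model (FRM), the
season-invariant baseline.  The smoothness pair `(λ_s, λ_t)` is chosen by
generalized cross-validation over a log-spaced ladder whose top rung is the
FRM itself.  Forecast skill is assessed by a leakage-aware rolling-origin
protocol: for each origin `n0`, training uses observations `1,…,n0−6` only
(the response is a forward weekly average, so the last six indices overlap
the week being predicted) and the model predicts observation `n0`.

Production data of this kind are commercially sensitive, so the package
ships a synthetic-data generator that emulates the study design — minute- to
two-minute-cadence sensor streams, seasonal cycles with day-level AR(1)
weather, daily yields driven through the model integral by known smooth
coefficient surfaces, and weekly facility holidays — giving every stage of
the pipeline a testable ground truth.

## A worked example

```python
import numpy as np
from cropfda import (
    make_synthetic_study, center, functionalize, select,
    SelectionGrid, surface_grid,
)
from cropfda.experiments import default_specs, pipeline_samples

ds = make_synthetic_study(seed=1, cadence_minutes=10, n_years=6)
samples = pipeline_samples(ds, subsample_step=6)     # n = 280 harvests
centered, info = center(samples)
vcfrm, _ = default_specs(lag_days=ds.lag_days)
fs = functionalize(centered, vcfrm.s_basis, rho=1.0)
grid = np.logspace(-4, 6, 11)
res = select(fs, vcfrm, SelectionGrid(grid, np.append(grid, np.inf)),
             centering=info)
print("chosen (lambda_s, lambda_t):", res.chosen)
print("edf: %.1f  rss: %.2f" % (res.fit.edf, res.fit.rss))

est = surface_grid(res.fit, 0, np.linspace(0, 60, 61), np.linspace(30, 300, 91))
i, k = np.unravel_index(np.argmax(est), est.shape)
print("temperature surface peak at s=%.0f d before harvest, t=%.0f d of season"
      % (np.linspace(0, 60, 61)[i], np.linspace(30, 300, 91)[k]))
```

prints

```
chosen (lambda_s, lambda_t): (10000.0, 1000000.0)
edf: 85.1  rss: 38.88
temperature surface peak at s=43 d before harvest, t=150 d of season
```

The selected smoothness keeps about 85 effective parameters across the two
surfaces and the seasonal intercept; the
estimated temperature effect peaks 43 days before harvest around day 150 of
the season — the generating truth places the positive temperature bump at
(45 d, 150 d), so the pipeline localizes it to within a couple of days in
lag and exactly in season.

The `examples/` directory contains short narrative scripts, one per
capability: generating a synthetic study, fitting and plotting coefficient
surfaces, choosing smoothness by information criterion, and the rolling
forecast comparison against the FRM baseline.  A thin command line
(`cropfda simulate|preprocess|fit|select|forecast|report`) drives the same
library functions from a YAML config; crop presets are
`strawberry_defaults()` (60-day lag, packages/day at 250 g per package) and
`tomato_defaults()` (80-day lag, kg/day).

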