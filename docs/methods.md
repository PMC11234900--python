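# Methods

## Model

For harvest observation *i* at day-of-season *t_i*, the package models the
7-day forward moving-average yield as

y_i(t_i) = α(t_i) + Σ_{j=1}^{J} ∫₀ᴸ x_ij(s) β_j(s, t_i) ds + ε_i,
ε_i ~ (0, σ²) independent,

with s the lag in days before harvest, L the lag-window length (60 d for
strawberry-style data, 80 d for tomato-style), and x_ij the j-th
environmental factor over that window.  Both y and the x curves are centered
by their training-sample means before fitting, so no scalar intercept
appears.  The coefficient surfaces carry the science: β_j(s, t) is the
marginal effect on the weekly yield of a unit of factor j experienced s days
before a harvest occurring at season-time t, assumed smooth in both
arguments and linear at fixed (s, t).

Each surface is expanded in a tensor product of cubic B-spline bases,
β_j(s,t) = φ(s)ᵀ B_j ψ(t) (defaults: 10 basis functions per axis, equally
spaced interior knots, clamped boundaries), and each predictor curve in the
s-basis, x_ij(s) = Σ_m c_ijm φ_m(s).  The model integral then reduces to the
bilinear form (G c_ij)ᵀ B_j ψ(t_i) with G the s-basis Gram matrix, so the
model is linear in vec(B) and the penalized least-squares problem

min ‖y − Z vec(B)‖² + Σ_j [ λ_s ∬ (∂²β_j/∂s²)² + λ_t ∬ (∂²β_j/∂t²)² ]

has the closed form vec(B̂) = (ZᵀZ + Λ)⁻¹ Zᵀy, with
Λ = blockdiag_j [ λ_s (P_s ⊗ G_t) + λ_t (G_s ⊗ P_t) ].  Gram (G) and
second-derivative penalty (P) matrices are computed by fixed-order
Gauss–Legendre quadrature per inter-knot interval, which is exact for the
piecewise-polynomial integrands; the system is solved by Cholesky
factorization (problem sizes are a few hundred parameters).  Model
complexity is summarized by the effective degrees of freedom
edf = tr(Z (ZᵀZ+Λ)⁻¹ Zᵀ).

The t-constant special case — the classical functional regression model
(FRM) — is implemented as a one-function constant t-basis; it is the
baseline that cannot express seasonal variation of the environmental effect.

### The seasonal intercept α(t)

Centering by global means does not make the varying-coefficient model
self-consistent: subtracting the mean predictor profile x̄_j(s) removes the
term Σ_j ∫ x̄_j(s) β_j(s,t) ds from the linear predictor, and that term
varies with t whenever β_j does.  In the synthetic studies this nuisance is
comparable in size to the response standard deviation; without a place to
live it is absorbed into β̂ and overwhelms the surfaces.  The package
therefore includes a smooth seasonal intercept α(t), expanded in the t-basis
and left essentially unpenalized (a 10⁻⁶ ridge for numerical definiteness).
For the FRM the analogous term is constant and centering alone removes it,
so the baseline carries no intercept.  `VCFRMSpec(intercept=...)` defaults
to off for the bare estimator and on in the pipeline configuration.

## Smoothness selection

(λ_s, λ_t) are chosen by exhaustive grid search under generalized
cross-validation, GCV = n·RSS/(n − edf)², the standard prediction-oriented
criterion for linear smoothers; an AIC-type alternative
(n·log(RSS/n) + κ·edf) is available behind the same interface.  The default
ladder is 9 log-spaced values 10⁻⁴…10⁴ per axis; the packaged experiments
use 10⁻⁴…10⁶ plus one further rung at λ_t = ∞, which is scored as the exact
FRM (t-constant surfaces, no intercept).  The ∞ rung matters: the
second-derivative t-penalty leaves surfaces linear in t (and the intercept
free) even as λ_t → ∞, so without it the varying model retains a few dozen
unpenalized degrees of freedom that cost real forecast accuracy when the
truth has no seasonal structure.  With the FRM on the ladder, selection
collapses the model family gracefully: on seasonally constant synthetic
truth the ∞ rung is chosen in most replicates (median VCFRM/FRM test-RMSE
ratio 1.0), while on seasonally varying truth a finite λ_t wins.  Ties break
toward the smoother fit (larger λ_s, then larger λ_t).

Predictor functionalization has its own weight ρ (penalized regression of
the hourly window on the s-basis); it is selected per window by GCV by
default and fixed to ρ = 1 in the bulk experiments for reproducibility — at
1 440 hourly cells per 60-day window the fit is insensitive to ρ over
several orders of magnitude.

## Forecast protocol

Rolling-origin evaluation mirrors grower practice: at origin n0 the training
set is observations 1,…,n0−6 and the test set the single observation n0.
The 6-index gap is what prevents leakage — the response is a forward 7-day
moving average, so y at indices n0−5,…,n0−1 shares days with the week being
predicted.  Centering and smoothness selection are computed inside the
training window only (selection at the first origin, refreshed every 30
origins by default).  Setting the gap to 0 deliberately admits the overlap
(and the origin itself) into training; the packaged leakage-contrast
experiment shows that the leaking protocol scores markedly better
(RMSE ratio ≈ 0.3), which is precisely the optimism the gap removes.

Accuracy trajectories use the windowed RMSE exactly as defined for this
protocol: RMSE_i = sqrt((1/30) Σ_{j=i…i+30} (y_j − ŷ_j)²) — note the sum has
31 terms over a divisor of 30, so a constant error e maps to
|e|·sqrt(31/30) ≈ 1.0165·e; the implementation preserves this as-printed
convention and the tests pin it.

## Synthetic data

The generator emulates the study design end-to-end so that every stage has a
known ground truth:

* **Sensors.** Temperature and solar radiation at 1-minute cadence (the
  study cadence; experiments use 10-minute cadence, statistically equivalent
  after hourly averaging): an annual sinusoid plus day-level AR(1) noise
  interpolated to cadence.  Defaults — temperature 18 ± 5 °C annual cycle,
  daily sd 3.0 °C, AR(1) 0.6 (a natural-light greenhouse moderates the
  seasonal swing while weather drives day-to-day variation); radiation
  14 ± 7 with daily sd 5.0, AR(1) 0.4, clipped at zero (overcast/clear-day
  contrast).  No within-day structure is modeled: the pipeline's hourly
  averaging followed by 60-day smoothing discards it.
* **Truth surfaces.** Sums of anisotropic Gaussian bumps, sign-mixed within
  the season — a positive temperature effect ~45 d before harvest and a
  negative one ~15 d before, in overlapping parts of the season; the
  radiation surface mirrored (positive near harvest, negative deep in the
  lag).  Bump widths are 12–15 d in lag and 80–90 d in season, the scale of
  the features such models are used to find.
* **Yields.** Daily yield = Σ_j ∫ x_j(s) β_j(s,t) ds + baseline + ε, with
  x_j the daily-mean environment (piecewise constant) and the integral
  computed by per-day Gauss–Legendre quadrature; ε is homoscedastic Gaussian
  with sd calibrated to 10 % of the noiseless signal sd.  One weekday per
  week is a facility holiday (yield row absent).  The noiseless signal is
  recorded for tests.

What the generator does **not** emulate: crop physiology, irradiance
transfer, within-day microclimate, heteroscedastic or serially correlated
yield noise, and holiday patterns beyond a fixed weekday.  Passing tests
demonstrate that the estimator recovers the structures this generator
produces; real facilities add misspecification the synthetic studies cannot
probe.

## Experiment design and problem sizes

* **Surface recovery** (`experiments.surface_recovery`): six seasons pooled
  on the day-of-season axis, harvests subsampled to every 6th day, n ≈ 280.
  Multi-season pooling is essential, not cosmetic: with a single season
  every season-time is visited once and the lag windows are overlapping cuts
  of one series (x(s; t) ≈ f(t − s)), leaving the surface unidentified along
  diagonal shifts no matter how λ is chosen — session diagnostics showed
  oracle-λ errors above 2 in that design, versus ~0.27 with six seasons.
  Cross-year replication at each season-time is also how the real studies
  of this kind are designed.  Error is the relative L2 distance between the
  estimated and generating surfaces, pooled over both predictors, on
  s ∈ [0, 60] × t ∈ [30, 300]; the outer ~30-day strips of the season axis
  are excluded because penalized spline surfaces are unreliable where data
  thin out at domain boundaries.  Peak localization is the argmax of the
  temperature surface; its season coordinate is the least stable quantity
  (median error ~10 d across seeds, occasional 40–50 d excursions when the
  selected λ_t flattens the ridge), which is why the reproduction script
  reports medians over five replicates.
* **Model comparison**: 20 replicates per truth type, each a fresh 4-season
  study (the flagship study length) subsampled to every 4th harvest,
  rolling-origin forecasts over the ~70 final-season origins, selection at
  the first origin.
* The moving-average response biases the estimand slightly: y averages 7
  consecutive daily yields, so the effective surface is (1/7) Σ_k β(s+k, t)
  — features shift ~3 d toward the harvest and the deepest 6 lag-days blur.
  This is inherent to the protocol, not the estimator, and is part of why
  recovery is measured against a 0.35 rather than a 0.05 threshold.

## Numerical choices and degenerate inputs

* Quadrature: Gauss–Legendre with ⌈degree/2⌉+1 nodes per inter-knot
  interval — exact for all Gram/penalty integrands; no adaptive integration
  in the hot path.
* Penalized solves: Cholesky on ZᵀZ + Λ; a non-positive-definite system
  raises with the smallest eigenvalue rather than silently regularizing.
* Window smoothing requires ≥ n_basis non-missing cells at ρ = 0 (else a
  singular-fit error suggesting ρ > 0) and skips missing cells; lag windows
  missing more than 24 hourly cells are dropped with a logged reason, not
  imputed.
* Hourly binning is half-open ([h, h+1)); hours with no samples are missing,
  never zero.  The moving average divides by the count of available days and
  requires at least 4 of 7 present, so a near-empty week cannot pose as a
  weekly average.
* Season time is (harvest date − season origin) mod 365, pooling years onto
  one axis; predictions at season times outside the fitted t-basis domain
  raise instead of extrapolating.
* Selection ties break toward the smoother model; the criterion table is
  bit-reproducible on fixed input.

## Known limitations

* The surface near the lag-window edges (s ≈ 0 and s ≈ L) and the season
  edges inherits spline boundary variance; interpret contour maps away from
  the margins.
* α(t) and the surfaces' seasonal structure are partially confounded through
  the seasonal component of the predictors; the intercept removes the
  centering nuisance but localization of seasonal features remains the
  hardest part of the problem (see the peak-location medians above).
* GCV treats residuals as exchangeable; the moving-average response has
  serially correlated errors, which GCV partly absorbs by over-smoothing λ_t.
* Estimation assumes homoscedastic, uncorrelated errors (unweighted least
  squares); no confidence bands are provided for β̂.
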