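# Methods

## The model

Counts `y_ap` for age group `a = 1..I` and period `p = 1..J` are modelled
with an exponential-family distribution (Poisson by default, with a
log-exposure offset so the linear predictor is a log rate):

    d(mu_ap) = eta_ap = beta_0 + h_A(a) + h_P(p) + h_C(c),

where the cohort index is `c = M*(I - a) + p` and `M` is the ratio of
age-interval to period-interval width (`M = 5` for five-year age bands with
annual periods).  Because cohort = period − age, the three linear trends are
confounded.  The package fits the identifiable Holford reparameterisation

    eta_ap = beta_0 + beta_1*a + beta_2*p + f_A(a) + f_P(p) + f_C(c),

with the cohort slope dropped by default (a flag selects age or period
instead; the fitted `eta` is invariant to the choice, and the retained
slopes then absorb part of the dropped trend, so they must not be
over-interpreted).  Each curvature `f_T` satisfies `sum_t f_T(t) = 0` and
`sum_t t*f_T(t) = 0`; the constraints are imposed exactly by
reparameterising onto an orthonormal basis of the constraint null space
(the same conditional law as conditioning-by-kriging projection, computed
once by QR instead of per-sample).

Internally all covariates use centred, unit-spaced integer indices; age
midpoints, years and birth-years are labels only (numerical conditioning;
the index form is also what makes the cohort arithmetic exact).

A caveat the equal-interval intuition misses: on aggregated grids with
`M > 1`, any function of `c mod M` coincides with a function of
`p mod M` on the observed cells, so the full-index design is rank deficient
by a further `M − 1` beyond the Holford three.  This is the "artificial
cyclic pattern" that motivates second-derivative smoothing: both smoothers
below penalise exactly those high-frequency directions, which is why their
fits are well defined where the unpenalised model is not.

## School 1: penalised regression splines

Each curvature is expanded in a cubic spline basis, `f = Z @ gamma`, with
either a cubic regression spline (CRS: cardinal natural-cubic,
value-at-knot parameterisation) or cubic B-splines (BS: clamped knot
vector).  Knots are equally spaced over the fitted range; defaults are
10/10/12 knots for age/period/cohort.  Fitting maximises

    l(beta, gamma, theta) - sum_T lambda_T * gamma_T' S_T gamma_T,

with `S = int g'' g''^T dx` computed exactly by per-interval Simpson
quadrature (the integrand is piecewise quadratic).  `S` is symmetric PSD
with a null space of dimension exactly two (straight lines).  For BS a
second-order coefficient-difference penalty `D'D` is available; it has the
same tri-diagonal form as the RW2 structure matrix and is what the
cross-school equivalence uses.  The solver is penalised IRLS with step
halving; convergence when the relative change in penalised deviance falls
below 1e-8, cap 200 iterations.  Note the Hessian of the objective is
`X'WX + 2*lambda*S`, so the implied Gaussian prior on `gamma` has precision
`2*lambda*S` — the factor of two is fixed by writing the penalty without a
half, and propagates consistently into the covariance and the REML
criterion.

Smoothing parameters are chosen by coordinate-wise search over a 31-point
log-lambda grid on [1e-4, 1e8] with golden-section refinement (two sweeps;
grid ties break toward the larger lambda, i.e. the smoother fit).  The
criterion is GCV (`n*D/(n-edf)^2`) for gaussian data and a
Laplace-approximate REML for count families.  On pure noise either
criterion occasionally fits ~1 effective degree of freedom to a lucky draw;
flatness of the selected fit is a median property across replicates, and is
tested as such.  The negative-binomial dispersion, when requested, is
estimated by an outer bounded search on log theta.

Intervals are `eta_hat ± 1.96*SE` with `SE^2` the quadratic form of the
design row with the Bayesian posterior covariance `(X'WX + 2P)^{-1} * phi`.
Forecasts evaluate the basis beyond the fitted range; both basis kinds
extend linearly (value plus boundary slope), matching the natural-spline
extension, and the extrapolation distance is recorded with the prediction.
These intervals are confidence intervals for the smooth mean and carry no
smoothing-parameter uncertainty — which is precisely the behaviour the
comparison study interrogates.

## School 2: RW2 random-walk priors

Each curvature field (evaluated on its full index set, extended when
forecasting) gets an intrinsic second-order random-walk prior

    pi(f | tau) ∝ tau^((n-2)/2) * exp(-tau/2 * sum (Delta^2 f)^2),

i.e. an intrinsic GMRF with structure matrix `R = D'D` of rank `n - 2`
(interior stencil 1, -4, 6, -4, 1).  The two Holford constraints remove
exactly the null space of `R`, so the constrained prior is proper and the
`(n-2)/2` normalising power is the correct one for the tau update.  The
precision carries a penalised-complexity prior — exponential on
`sigma = tau^{-1/2}` with rate `kappa = -ln(alpha)/U`, calibrated by
`P(sigma > U) = alpha`; defaults `U = 1, alpha = 0.01`, with `U` in
{1, 3, 6} exercised by the study roster.  Intercept and slopes get
zero-mean gaussian priors with variance 1e6.

Inference is MCMC, written so every piece can be validated against closed
forms:

- the whole latent gaussian block (betas plus the three constrained
  fields) is proposed jointly from a gaussian approximation at the
  conditional mode (damped Newton, warm-started and cached per tau) with a
  Metropolis–Hastings correction; for gaussian observations the proposal
  is the exact conditional, so the update is Gibbs;
- each log-precision takes a random-walk Metropolis step whose scale
  adapts toward 0.44 acceptance during burn-in only (so the post-burn-in
  chain is a fixed Markov kernel and runs are reproducible by seed);
- defaults 20,000 iterations, 5,000 burn-in, thinning 5; the bundled
  studies use a reduced budget (2,600/600/4, 500 retained draws), which is
  enough for medians and 95% quantiles of a near-gaussian posterior —
  quantile noise is then the dominant small error and is covered by the
  Monte-Carlo tolerances the tests compute.

Forecasting extends the period field by `t` nodes and the cohort field by
the `t` new cohorts; unobserved cells contribute no likelihood.  Under the
prior the forecast of a pure RW2 continues the line through the last two
nodes with variance `tau^{-1} t(t+1)(2t+1)/6` — cubically growing, which is
why RW2 forecast intervals widen much faster than spline ones.

Point predictions are posterior medians; uncertainty is the 2.5%/97.5%
posterior quantiles of the per-cell linear predictor.

## Equivalence of the two schools

Writing the penalised likelihood as likelihood × `exp(-lambda g'Sg)`
exhibits the penalty as an improper gaussian prior with precision
`2*lambda*S`, rank `T - 2`.  With a saturated basis (one coefficient per
index) and the difference penalty, `S = R`, and the correspondence is
`lambda = tau/2`: the penalised fit equals the RW2 posterior mode at fixed
tau exactly (to 1e-8 in the tests, after matching the vague beta prior via
the spline's `fixed_ridge` option).  The practical difference between the
schools is therefore not the smoother but what happens to the smoothing
parameter: selected and then frozen (spline) versus integrated over (RW2).

## Scoring

MAE and MSE on the linear-predictor (log-rate) scale, and the 95% interval
score `IS = width + (2/alpha)*(escape distance)`, averaged over cells (and
replicates), with mean width and empirical coverage alongside.  The
averaging (rather than summing) makes scores comparable across windows of
different sizes.  Predictions are scored against the observed empirical
log-rates (with a +1/2 continuity correction applied only for this purpose,
never in fitting); the report records which truth convention was used, and
a noiseless-generator convention is available for recovery checks.
Coverage of the smooth-mean intervals against noisy observations is well
below nominal by construction — that shortfall, and how the two schools
price it through the interval score, is the object of the comparison.

## Synthetic data

The generator mimics rare-event mortality surveillance: single-year ages
10–84 and periods 2000–2020, fixed population 750,000 per single-year cell,
Poisson counts (negative-binomial optional), then aggregation into
five-year bands modelled at midpoints 12.5, ..., 82.5 (`M = 5`), with
counts and exposure summed (summing preserves expected counts).  The true
surface is intercept −11.3 (so aggregated cells average tens of events),
age slope 0.02 and period slope 0.005 per single-year index, plus three
smooth curvatures supplied as shape callables on [0, 1] with a scale each:
a concave age bump (quadratic + sine, scale 1.2), `sin(2.5*pi*u)` in period
(scale 0.2) and `sin(2*pi*u)` plus a quadratic in cohort (scale 0.35).  The
period and cohort shapes were chosen so their slopes keep changing through
the forecast window: a truth whose trend conveniently flattens at the
boundary makes linear extrapolation exact and erases the very differences
between the schools the study exists to measure.  All shapes are projected
onto the constraint space of the grid they are evaluated on, so "true
curvature" is well defined at any aggregation level.

What the generator does not emulate: real population dynamics (exposure is
constant), age-dependent exposure, reporting artefacts, and any structural
break in the trends.  Passing tests therefore show that the estimators
behave as designed under a smooth, correctly specified truth — not that
either school is robust to misspecification.

Fit window 2000–2017, forecast 2018–2020, N = 100 replicates by default;
the bundled comparison runs N = 20 with one CRS spline and one RW2 (U = 1)
model, which reproduces the qualitative orderings (RW2 forecasting interval
score lower; RW2 widths larger; RW2 coverage higher; MAE/MSE
indistinguishable) in a few minutes on one CPU.  Per-replicate seeds expand
from the global seed by a fixed affine counter, so studies are
byte-reproducible end to end.

## Numerical choices and degenerate inputs

- PIRLS tolerance 1e-8 on relative penalised deviance, 200-iteration cap,
  step halving; |eta| > 30 on the log scale flags separation.
- Newton mode-finding tolerance 1e-9 on the step, cap 50; the posterior
  Hessian is used unregularised because the constrained parameterisation is
  already full rank (the vague beta precision 1e-6 bounds the flattest
  directions).
- Grid ties in smoothing selection break toward the larger lambda.
- Missing counts (NaN) are allowed anywhere and simply drop out of the
  likelihood; datasets with no observed cells, non-positive exposure at
  observed cells, ragged aggregation bands, fewer than 4 knots, more knots
  than distinct values, and fields shorter than 3 are rejected with
  explicit errors.
- The +1/2 continuity correction is used only when forming empirical
  log-rates for display or scoring, never in model fitting.

## Known limitations

- Thin-plate splines, tensor-product smooths, RW1-based fitting and
  Lee–Carter models are out of scope (the RW1 structure matrix is
  generated for completeness but untested beyond its identities).
- The spline covariance conditions on the selected lambda; intervals are
  known to be optimistic.  That is a property under study, not a defect to
  be patched here.
- MCMC on large grids is the slowest path; the latent block is updated
  jointly, so cost grows with the cube of the latent dimension (about 130
  on the bundled study grid, which is unproblematic).
- Real-data workflows assume a complete rectangular age × year table.
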