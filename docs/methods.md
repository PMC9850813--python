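# Methods

This note documents the models implemented in `naspatial`, the sampler,
the synthetic-data generator and its defaults, the numerical choices, and
the known limitations.  It is written for someone who wants to understand
*why* the package behaves the way it does, not just what it computes.

## The scientific problem

Registry studies of healthcare access often ask an areal causal question:
does a higher density of physicians in a municipality reduce the rate of
late-stage cancer diagnoses there?  The observable data are municipality
counts: observed late-stage cases `Y_i`, an exposure `X_i` (physicians per
10,000 inhabitants), covariates `Z_i`, and the age-sex structure of the
population.  Two obstacles stand between such data and a causal estimate:

1. municipalities differ in size and demography, so raw counts are not
   comparable — handled by indirect standardization;
2. unobserved *spatially structured* confounders (working conditions,
   facility quality, remoteness) influence both where physicians settle
   and diagnostic outcomes — handled by the neighbourhood-adjustment
   model.

## Indirect standardization

Pooled reference rates are computed for four age-sex strata (females 0–74,
females 75+, males 0–74, males 75+):

    r_s = (sum_i C_is) / (sum_i P_is),      E_i = sum_s r_s P_is.

`E_i` is the count area i would see if it experienced the pooled rates
given its own population structure; `RR_i = Y_i / E_i` is the standardized
incidence ratio.  With internally computed rates the procedure is
calibrated — `sum_i E_i` equals total cases exactly — which the tests
assert at 1e-9 relative tolerance.  Expected counts pool the whole study
window; per-year standardization is out of scope.

Quartile aggregation of RR by exposure uses sample quantiles with linear
interpolation, ties joining the lower group, and aggregates as
`(sum Y)/(sum E)` within groups so the whole-sample ratio is conserved.
Displayed percentages round half-away-from-zero to one decimal.

## The BYM model

Late-stage counts are modelled as

    Y_i ~ Poisson(mu_i),
    log mu_i = log E_i + beta0 + beta_x X_i + gamma' Z_i + phi_i + theta_i,

with `phi` an intrinsic CAR (ICAR) structured effect on the contiguity
graph — precision `tau_phi (D - W)`, sum-to-zero per connected component —
and `theta` iid `N(0, sigma_theta^2)`.  Coefficients have `N(0, 10^2)`
priors.  The variance hyperpriors are inverse-gamma(1, 0.01) on
`sigma_theta^2` and on `tau_phi^{-1}`, a common weakly-informative
disease-mapping default, exposed in the config.  A proper-CAR variant
(`tau (D - alpha W)`, `0 <= alpha < 1`) is available through the config
because the appropriate variant is a modelling choice, not a data
question.  Islands (degree-0 areas) carry only the unstructured effect;
their smoother rows are identity and their proper-CAR diagonal is set to
one so every matrix stays well defined.

The exposure stays on its natural per-10,000 scale, so `beta_x` is the
log-rate change per one physician per 10,000 and `exp(beta_x)` the
relative risk per unit increase.

## The neighbourhood-adjustment (NA) model

An unmeasured spatial confounder `U` correlated with `X` biases the naive
estimate of `beta_x` by `B(X) = E[U | X]` — the part of U's effect the
regression attributes to the exposure.  The NA model removes this bias by
modelling `(X, U)` jointly and imputing `U` as missing data inside the
Gibbs sampler.  The concrete coupling implemented here is linear-Gaussian
through the row-stochastic neighbourhood smoother `S = D^{-1} W`:

    U | X ~ N(delta * S^order X, Q_U^{-1}),   Q_U = tau_U (D - alpha_U W),

with `delta ~ N(0, 10^2)` sampled, and the outcome model

    log mu_i = log E_i + beta0 + beta_x X_i + gamma' Z_i + U_i.

This makes the bias functional explicit, `B(X) = delta * S^order X`, and
realizes the qualitative description of the method — joint spatial
modelling of exposure and confounder with different spatial ranges,
permitting exposure–confounder correlation — in a form that is fully
testable.  `U`'s prior must be proper (the coupling mean is a genuine
regression target); requesting an ICAR confounder prior is a contract
error.

### Identification

Because `S` wipes fine-scale variation, `S X` carries only the smooth
component of the exposure.  The coefficient pair `(beta_x, delta)` is then
separated by the *fine-scale* variation of `X` — the component `X - S X`
that the confounder's conditional mean cannot follow.  Two consequences:

* The method needs the exposure field to contain spatial variation at a
  range at least as large as the confounder's **and** a fine-scale
  component of its own.  The `NaSpec` records the assumed ranges and warns
  when the confounder's configured range exceeds the exposure's; the
  generator likewise warns (an `IdentificationWarning`) when a simulated
  confounder noise field is smoother than the exposure.  When the
  assumption is violated, de-biasing degrades — the smooth part of the
  confounding is then indistinguishable from the exposure effect.
* Sampling `delta` is equivalent to adding the collinear covariate `S X`
  to the regression.  Even when the true `delta` is zero the coupled fit
  therefore pays a variance-inflation factor of roughly
  `1/(1 - R^2(X, SX))` on `beta_x` relative to the uncoupled fit — about
  1.3 at the default exposure smoothness.  The coupled and uncoupled
  posteriors agree in mean (within posterior uncertainty) but not exactly
  in spread; the tests assert precisely this, and no stronger
  distributional identity, because no stronger identity holds.

## Sampling

Both fits are Metropolis-within-Gibbs samplers over the blocks
(coefficients; latent field(s); variance parameters; coupling):

* **Non-conjugate blocks** (coefficients, `phi`, `theta`, `U`) use
  Metropolis–Hastings with a Gaussian proposal from the local quadratic
  (Newton) approximation of the log full conditional, corrected by the
  reverse-proposal density.  Near the mode of a Poisson log-link
  conditional these proposals are nearly exact, giving acceptance rates
  around 0.6–0.98 and low autocorrelation; under the Gaussian test-hook
  likelihood they *are* the exact conditionals, which the oracle tests
  exploit.  Latent fields update either as one n-dimensional block (dense
  Cholesky of `diag(h) + Q`; default, n is a few hundred) or site-wise
  over a greedy graph colouring.
* **Initialization**: each block starts at its conditional mode (damped
  Newton).  Quadratic proposals are only valid guides in the high-mass
  region; started far away, the reverse-proposal correction rejects
  essentially forever.
* **Conjugate blocks**: `sigma_theta^2`, `tau_phi`, `tau_U` have
  inverse-gamma/gamma Gibbs updates (the ICAR shape uses the rank
  `n - #components`); `delta` has a Gaussian Gibbs update.
* **Translation moves**: the posteriors contain weakly identified
  directions along which the linear predictor is invariant —
  `(beta0, U)`, `(beta_x, delta, U)` in the NA model and
  `(beta_x, phi)` in the BYM model.  Plain blockwise updates random-walk
  along these ridges and mix poorly.  A scalar random-walk MH move along
  each ridge (adapted toward 0.44 acceptance during burn-in, frozen
  after) removes the problem; measured chunk-to-chunk drift of the
  exposure coefficient falls from ~0.15 to <0.01 on confounded problems.
* **ICAR constraint**: `phi` is re-centred per connected component after
  each sweep (centering-on-the-fly), the standard treatment of the ICAR
  impropriety; no diagonal jitter is used anywhere.
* Chains are single by default and bit-reproducible given the seed;
  iteration counts follow the 10,000-with-1,000-burn-in convention
  (saved draws = iterations − burn-in).  Divergence (non-finite
  log-likelihood) raises an error naming the iteration.

## Posterior summaries

Mean coefficient = arithmetic posterior mean; 95% equal-tailed credible
intervals from sample quantiles (linear interpolation) — chosen over HPD
for exact reproducibility; percent change per unit exposure
`(1 - exp(beta)) * 100`; geometric-mean relative risk `exp(mean beta)`;
the population-average exposure–response curve is a Gaussian kernel
density of the `exp(beta)` draws (point-mass representation for
degenerate draws).  Display rounding: coefficients 3 decimals, RR 2,
percent change 1.  All summaries are pure functions of the draws.

## The synthetic-data generator

No public registry data exist for this design, so the generator emulates
the study rather than any particular country's geography:

* **Graph**: Delaunay triangulation of uniform random points (default;
  mean degree ≈ 6, connected), a near-square grid, or a supplied edge
  list.  Default 356 areas, matching the administrative division count of
  the emulated design.
* **Populations**: log-normal with median 5,200 and log-sd 1.3 (matching
  the reported municipal median and interquartile spread), split into the
  four strata with fixed shares 0.38/0.12/0.38/0.12.
* **Stratum rates**: 0.0020/0.020/0.0025/0.025 cases per person over the
  pooled window — ≈ 0.7% cumulative incidence, ≈ 40 late-stage cases in a
  median municipality, total ≈ 30,000 cases at full size, the order of
  the emulated national census.
* **Exposure**: mean 1.4 and sd 0.45 per 10,000 (median and IQR of the
  reported specialist-density distribution), built as 70% smooth regional
  field (proper CAR, alpha 0.95, one smoothing pass) plus 30%
  municipality-level idiosyncratic variation, clipped at zero.  The
  idiosyncratic share reflects that staffing counts in small
  administrative units are far from spatially exact, and it fixes the
  fine-scale variance that identifies the NA model at a stable value
  across draws.
* **Confounder**: `U = delta * S X + eps` with coupling `delta = 0.3` and
  `eps` a short-range proper-CAR field (alpha 0.5) with sd 0.15.  The
  coupling produces an upward confounding bias of ≈ +0.2 on the naive
  exposure coefficient — large enough that de-biasing is measurable
  against replicate noise at the scaled-down study sizes the tests use.
* **Effects**: beta0 = 0, beta_x = −0.03 (a test point near the magnitude
  of published areal physician-density effects; an observational study
  has no ground truth to copy), gamma = (0.05, −0.05) on two iid
  standard-normal covariates.
* **Outcome**: `Y_i ~ Poisson(E_i exp(beta0 + beta_x X_i + gamma'Z_i + U_i))`,
  with `E_i` from the generator's own stratum rates via the
  standardization module and per-stratum case counts allocated
  multinomially in proportion to `r_s P_is`, so re-standardizing the
  synthetic strata is calibrated by construction.  A guard rejects
  configurations implying mean counts above 1e6.

What the generator does **not** emulate: real municipal geography or
adjacency, migration between areas, time trends within the pooled window,
non-Poisson overdispersion beyond the latent field, exposure measurement
error, or the real (unknown) confounding structure.  Passing recovery
tests therefore demonstrate internal consistency of the method under its
own assumptions, not correctness of any substantive epidemiological
claim.

## Problem sizes used in tests

The validation suite runs scaled-down designs chosen to keep the whole
suite reproducible on a single CPU while leaving each check statistically
decisive: 150-area replicates (10 of them, 6,000 iterations each) for the
de-confounding and precision comparisons, 100 areas with the full
10,000-iteration schedule for null recovery, 20–50 areas for
kernel-correctness and distributional checks, and a 5,000-area study for
the large-n oracle regression.  The acceptance script uses 5 replicates
of the 150-area design.

## Known limitations

* The NA coupling implemented here is one concrete member of the family
  of joint exposure–confounder models; it captures the mechanism
  (smoothed-exposure conditional mean, short-range proper-CAR residual)
  but other couplings would give different finite-sample behaviour.
* `beta_x` is identified by fine-scale exposure variation; for an
  exposure field with no idiosyncratic component the NA posterior widens
  sharply and the de-biasing advantage over an unadjusted fit can vanish
  at moderate sample sizes.
* Confounders at a *smaller* spatial scale than the exposure's fine
  structure are not removed — they are indistinguishable from the
  exposure effect in any areal design.
* The coupled model's intrinsic variance inflation at `delta = 0` (the
  collinearity cost described above) means the NA model is not a free
  upgrade: it buys bias reduction under confounding at the price of some
  precision when confounding is absent.  In the replicated synthetic
  experiments this cost roughly cancels the variance the NA model saves
  by anchoring the spatial field, so the NA and BYM credible-interval
  widths come out statistically comparable (the acceptance script
  reports both, along with the fraction of replicates where NA is
  narrower); the de-biasing, not a precision gain, is the method's
  measurable advantage here.
* ICAR re-centring per sweep is the standard approximate treatment of the
  intrinsic constraint; its effect is negligible at the graph sizes used
  here but it is not an exact constrained sampler.
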