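# Methods

## The distribution and its evaluation

The BXII-ME law composes the odds `W = G/(1−G)` of a moment-exponential
baseline `G(x) = 1 − (1+x/λ)e^{−x/λ}` with a Burr XII generator, giving
`F(x) = 1 − (1+W^β)^{−α}` on `x > 0`.  All three parameters are strictly
positive; `λ` carries the units of the data and the family is a scale
family in it, so standardized quantities (skewness, kurtosis, the
reliability `R_{s,κ}`) do not depend on `λ`.

The textbook formulas are numerically treacherous: `W` overflows once
`x ≫ λ`, and `G` suffers catastrophic cancellation near 0.  Everything is
therefore evaluated in log space:

* `log(1−G) = log1p(x/λ) − x/λ` (exact for all x), `G = −expm1(·)`;
* `log W = log G − log(1−G)`, and `log(1+W^β)` via a stable `log1p(exp(t))`
  with linear asymptotics for `t > 33`;
* the log-density is assembled from these pieces and exponentiated last.

With these choices the cdf, survival and log-density are finite and correct
over the whole double range (`cdf = 1`, `pdf = 0`, `logpdf` finite at
`x = 10⁴λ`), which the likelihood code path relies on.

### Quantile and random variates

The quantile has the closed form `x_q = −λ(1 + W₋₁(−1/(e(1+T))))` with
`T = [(1−q)^{−1/α} − 1]^{1/β}` and `W₋₁` the lower real branch of the
Lambert W function.  Near its branch point (q → 0, or small β) the closed
form loses several digits, so the Lambert value only seeds a Newton
iteration on the equivalent, well-conditioned root problem
`u − log1p(u) = log(1+T)` (convex in `u`, hence monotone convergence; the
start is floored at the branch-point expansion `u ≈ √(2 log(1+T))`).  Eight
iterations bring the quantile/cdf round trip below 1e−10 uniformly over the
tested parameter grid — in practice to machine precision.

Two samplers are provided and tested against each other: the default
inverse-cdf sampler (uniforms through the quantile) and a
gamma–exponential construction (`W₁ ~ Exp(1)`, `W₂ ~ Gamma(α,1)`, solve
`W(x)^β = W₁/W₂`), kept as an independent cross-validation route.  Both use
numpy `Generator` streams; identical seeds give identical draws.

## Moments by quadrature

Raw, incomplete and conditional moments, mean deviations, Lorenz/Bonferroni
curves and the truncated-moment characterization are all computed by
adaptive quadrature (QUADPACK through scipy) of their defining integrals,
after reducing to the unit-scale member via `u = x/λ` and applying the
scale law `E[X^r] = λ^r E[U^r]`.  Integrals are split at interior quantiles
(0.05–0.95) and at the 0.999999 quantile; the tail piece is integrated to
infinity separately, where the semi-infinite transformation handles the
exponential decay `S(x) ~ (x/λ)^{αβ} e^{−αβx/λ}`.  For truncation points
beyond the 0.999999 quantile the remainder is obtained by subtracting two
tail integrals rather than integrating a huge finite interval.  Quadrature
tolerances are 1e−10 (absolute and relative); an error estimate above
1e−6·max(1, |value|) raises a `NumericalError` instead of returning a
doubtful number.

Infinite-series expansions of these moments exist (nested alternating sums
over an exponentiated-ME expansion) but have no established convergence
guarantee, so they are deliberately not used; quadrature gives certifiable
accuracy and was verified against a 40-digit tanh-sinh oracle and
Monte-Carlo estimates in the test suite.

Central moments are formed from raw moments with compensated (`fsum`)
summation; the median always comes from the quantile function, never from
an expansion.

### Reliability of published reference values

The test suite compares the five descriptive quantities (mean, median, sd,
skewness, kurtosis) against a published reference table for 22 parameter
settings.  Means, medians and standard deviations reproduce within 0.5%
(except one row that is provably inconsistent with the scale-family laws
and is excluded).  The printed skewness and kurtosis of 17 of the rows,
however, disagree with high-precision quadrature by 0.5–9% (one skewness
even has the wrong sign at a near-symmetric setting).  Three independent
routes — scipy adaptive quadrature, 40-digit tanh-sinh quadrature, and
4×10⁶-draw Monte Carlo — agree with each other to ≲1e−9 relative and
against the β=1 closed form, so the discrepancies lie in the reference
values (most plausibly series truncation in their original computation).
The affected acceptance tests are kept at the 0.5% band and fail; the
frozen high-precision values in `tests/test_moments.py` are the ones this
package regards as correct.

## Estimation

Six estimators share one front-end: maximum likelihood (mle), maximum
product of spacings (mps), ordinary/weighted least squares on the empirical
cdf (lse, wlse), Anderson–Darling (ad) and Cramér–von Mises (cvm) minimum
distance.  Design choices:

* **Search space.** All methods optimise over `θ = log(α, β, λ)`, so
  positivity holds by construction, with L-BFGS-B and box bounds
  `|θ_i| ≤ 12` (parameters confined to `[6e−6, 1.6e5]`) to stop divergent
  excursions on uninformative samples.
* **Starts.** The automatic start uses the ME moment relation `E X = 2λ`:
  `λ₀ = mean/2`, `α₀ = β₀ = 1`; `multistart − 1` further starts are seeded
  Gaussian perturbations of it (default multistart 3; the simulation
  harness uses 1 for speed, which proved sufficient there).
* **Gradients.** The log-likelihood is analytic in the parameters, so its
  gradient is computed by complex-step differentiation (step 1e−200) —
  exact to machine precision, one evaluation per component.  With it the
  MLE satisfies the first-order conditions to ~1e−6; the distance criteria
  use L-BFGS-B's finite differences.
* **Stationarity vs. optimiser flags.** At very tight tolerances L-BFGS-B
  can end with a stalled line search at an already-stationary point; a
  result is recorded as converged if the optimiser succeeded *or* the final
  projected gradient is below 1e−5.
* **MPS ties.** A tied pair of observations makes a spacing zero and the
  log-spacing −∞; zero spacings are replaced by the log-density at the tied
  point (the standard adjustment for this estimator), so ties degrade the
  objective smoothly instead of breaking it.
* **Clamping.** Probability transforms inside AD/CVM/MPS logarithms are
  clamped to `[1e−12, 1−1e−12]`.
* **Standard errors.** Observed information: the Hessian of the negative
  log-likelihood at the MLE, computed as central differences of the
  complex-step gradient (relative step 1e−6), symmetrised by averaging
  (the pre-averaging asymmetry is ~1e−10 relative and is tested), then
  inverted.  How reference analyses obtained their standard errors is not
  stated anywhere authoritative; observed information is the conventional
  default and is what this package documents and tests (SEs shrink like
  1/√n empirically).  A non-invertible Hessian yields absent SEs with a
  warning, not an exception.

## Goodness of fit and model selection

On the probability transforms `u_i = F(x_(i))` of the ordered sample:
`W² = 1/(12n) + Σ(u_i − (2i−1)/(2n))²` and
`A² = −n − (1/n) Σ(2i−1)[ln u_i + ln(1−u_{n+1−i})]`, reported with the
standard small-sample modification factors `W* = W²(1 + 0.5/n)` and
`A* = A²(1 + 0.75/n + 2.25/n²)`.  Whether published analyses of this model
included those factors is not stated; this package includes them and says
so.  The K-S statistic uses the exact two-sided empirical formula and the
asymptotic Kolmogorov series for its p-value, without adjustment for
estimated parameters — matching common practice of reporting plain K-S
p-values next to fitted models; such p-values are conservative and are
labelled accordingly here.

Information criteria are the standard definitions
`AIC = −2l + 2k`, `CAIC = AIC + 2k(k+1)/(n−k−1)`, `BIC = −2l + k ln n`,
`HQIC = −2l + 2k ln ln n`, and reproduce the published BXII-ME
model-selection rows from their printed inputs to 4 decimals.  One
published table lists `−l` where its companion lists `−2l`; this package
works exclusively with `−2l` and the acceptance test documents the
conversion.

The TTT transform is `T_i = [Σ_{j≤i} x_(j) + (n−i) x_(i)] / Σ_j x_(j)`
against `i/n`; a concave curve diagnoses an increasing failure rate.  It is
a plotting diagnostic — no shape classification is attempted.

## Stress–strength reliability

`R_{s,κ} = (1/ν) Σ_{l=s}^{κ} C(κ,l) B(l + 1/ν, κ−l+1)` with `ν = α₁/α₂`,
evaluated through log-gamma/log-beta differences and compensated summation,
stable to `κ ~ 10³`.  The shared `β, λ` cancel; the tests verify this
against direct simulation at two different `(β, λ)` pairs.  Estimation of
`R_{s,κ}` from data is out of scope (only the population quantity has a
closed form here).

## Simulation harness and synthetic data

`run_simulation` draws `N` replicate samples at each size from a known
truth, fits the requested estimators, and reports empirical mean, bias
`(1/N)Σ(ĥ_i − h)` and MSE `(1/N)Σ(ĥ_i − h)²` per (method, size,
parameter).  Defaults follow the study conditions this harness exists to
examine: truth `(α, β, λ) = (0.25, 3, 3)` and the inverse-cdf generator.
The default grid is `N = 250` replications over sizes
`{20, 50, 100, 200, 400}` — a thinned version of the full
`N = 1000, n = 20(5)500` design, chosen so the whole experiment runs in
about a minute and a half on one core while preserving the qualitative
conclusion (bias and MSE fall monotonically in `n` for all six methods);
the full design is available by passing the larger grid.  One master seed
spawns independent substreams per (size, replicate); within a replicate all
methods see the same data.  Replicates whose optimiser did not converge are
dropped per cell and counted (`n_failed`); at these settings none fail.

`generate_fixture` writes one-value-per-line text plus a JSON sidecar
(parameters, seed) and stands in for external application datasets.  Being
exact draws from the model, such fixtures exercise everything except model
misspecification: passing tests demonstrate correctness of the machinery,
not that real lifetimes follow a BXII-ME.  Real data also bring ties,
rounding and censoring; ties are handled (MPS adjustment), censoring is not
supported (complete samples only).

## Known limitations

* At `n ≲ 20` the three parameters are weakly identified (α and β trade
  off); estimates can run to the search bounds and MSEs at such sizes are
  dominated by those excursions.  This is a property of the model, not the
  optimiser: the published qualitative claim (rapidly falling bias/MSE) is
  reproduced.
* The K-S p-value does not account for parameter estimation; for formal
  testing at fitted parameters a parametric bootstrap would be needed.
* No censored-data likelihood, no Bayesian machinery, and no analytic
  classification of density/hazard shapes (plot `pdf`/`hazard_suite`
  instead).
* Quadrature has been validated for moment orders `r ≤ 6` over the tested
  parameter grid; far more extreme shape parameters than the tested range
  (0.2–6) may need retuned splits.
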