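# bxiime

A Python toolkit for the **Burr XII–moment exponential (BXII-ME)
distribution**, a three-parameter lifetime law for strictly positive data
(failure times, survival times, waiting times) whose density can be
symmetric, right- or left-skewed, J-shaped or bimodal, and whose hazard can
be increasing, decreasing, bathtub or upside-down bathtub.  It is aimed at
statisticians and reliability/biostatistics practitioners who need a
flexible parametric alternative to the Weibull, gamma or log-logistic
families, together with the machinery to fit it, criticise the fit, and
study its estimators.

## The model

The moment exponential (length-biased exponential) baseline on `x > 0` has

```
g(x) = x e^{-x/λ} / λ²,        G(x) = 1 − (1 + x/λ) e^{-x/λ}.
```

Feeding the odds `W(x) = G(x)/(1−G(x))` of this baseline through a Burr XII
generator yields the BXII-ME cdf and pdf

```
F(x; α, β, λ) = 1 − [1 + W(x)^β]^{-α}
f(x; α, β, λ) = αβ g(x) G(x)^{β−1} (1−G(x))^{-β−1} [1 + W(x)^β]^{-α−1}
```

with shapes `α, β > 0` and scale `λ > 0`.  Setting `α = 1` gives the
log-logistic-ME sub-model, `β = 1` the Lomax-ME, and `α = β = 1` the ME
baseline itself.  The quantile function is closed-form through the lower
real branch of the Lambert W function:

```
x_q = −λ (1 + W₋₁(−1 / (e·(1+T)))),   T = [(1−q)^{-1/α} − 1]^{1/β}.
```

The package provides:

* `distribution` — cdf/pdf/log-pdf, survival, hazard, cumulative hazard,
  reversed hazard and elasticity; the Lambert-W quantile; two independent
  samplers (inverse cdf, and a gamma–exponential construction used as a
  cross-check);
* `moments` — raw/Mellin/incomplete/conditional moments by adaptive
  quadrature, descriptive summaries, mean deviations, Lorenz and Bonferroni
  curves, and a truncated-moment characterization check;
* `estimation` — maximum likelihood (with complex-step gradients and
  observed-information standard errors), maximum product spacings, least
  squares, weighted least squares, Anderson–Darling and Cramér–von Mises
  estimators behind one optimiser front-end;
* `gof` — AIC/CAIC/BIC/HQIC, the W*, A* and Kolmogorov–Smirnov statistics,
  and the total-time-on-test transform;
* `reliability` — the closed-form multicomponent stress–strength
  reliability `R_{s,κ}`;
* `simulation` — a seeded bias/MSE experiment harness and a synthetic
  fixture generator;
* a `bxiime` command-line interface over all of the above.

## Worked example

Generate a synthetic sample of 200 lifetimes from BXII-ME(0.25, 3, 3), fit
it by maximum likelihood, and assess the fit:

```
$ bxiime --quiet fixture --alpha 0.25 --beta 3 --lam 3 --n 200 --seed 42 lifetimes.txt
$ bxiime --quiet fit lifetimes.txt --method mle --seed 1
{
  "method": "mle",
  "alpha": 0.2277821032,
  "beta": 3.474181362,
  "lam": 2.968800032,
  "objective": -518.9058217,
  "n": 200,
  "converged": true,
  "iterations": 53,
  "se_alpha": 0.06695907202,
  "se_beta": 0.6345795221,
  "se_lam": 0.2032453325
}
```

The estimates sit within one standard error of the generating values
(α̂ = 0.228 ± 0.067 vs 0.25; β̂ = 3.47 ± 0.63 vs 3; λ̂ = 2.97 ± 0.20 vs 3).
Goodness of fit at the fitted parameters:

```
$ bxiime --quiet gof lifetimes.txt --alpha 0.2277821032 --beta 3.474181362 --lam 2.968800032
{
  "neg2ll": 1037.811643,
  "aic": 1043.811643,
  "caic": 1043.934092,
  "bic": 1053.706595,
  "hqic": 1047.815979,
  "wstar": 0.04758670124,
  "astar": 0.2635830789,
  "ks_stat": 0.04369185181,
  "ks_pvalue": 0.839736868
}
```

The K-S p-value of 0.84 and the small W*, A* distances say the fitted
BXII-ME is entirely compatible with the sample, as it should be here.  The
information criteria are the numbers one would compare across candidate
models fitted to the same data (smaller is better).

Population quantities come from the same library:

```
$ bxiime --quiet summary --alpha 0.25 --beta 3 --lam 3
{
  "mean": 8.746780702,
  "median": 7.482460583,
  "sd": 4.579848742,
  "skewness": 1.893943373,
  "kurtosis": 8.539211679
}
$ bxiime --quiet reliability --s 2 --kappa 4 --alpha1 0.5 --alpha2 1
{
  "s": 2,
  "kappa": 4,
  "reliability": 0.8
}
```

The last line is the probability that at least 2 of 4 identical components
with BXII-ME(0.5, β, λ) strengths survive a common BXII-ME(1, β, λ) stress —
exactly 0.8, independent of β and λ, which cancel in the closed form.

An estimator-comparison experiment (empirical bias and MSE of all six
methods across sample sizes, as a tidy CSV):

```
$ bxiime simulate --alpha 0.25 --beta 3 --lam 3 --sizes 20,50,100,200,400 \
    --reps 250 --methods mle,mps,lse,wlse,ad,cvm --seed 1 --out sim.csv
```

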