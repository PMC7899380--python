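"""Parameter estimation for the BXII-ME distribution.

Six classical estimators share one optimiser front-end: maximum likelihood
(mle), maximum product of spacings (mps), ordinary and weighted least
squares on the empirical cdf (lse, wlse), and the Anderson-Darling (ad) and
Cramer-von Mises (cvm) minimum-distance criteria.  All are optimised over
log-parameters, so positivity holds by construction, with a quasi-Newton
(L-BFGS-B) search and a seeded multistart.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import optimize

from .distribution import Params, Sample, as_params, cdf, logpdf, pdf
from .exceptions import DomainError

__all__ = [
    "METHODS",
    "EstimationConfig",
    "FitResult",
    "log_likelihood",
    "objective",
    "fit",
    "standard_errors",
]

Method = Literal["mle", "mps", "lse", "wlse", "ad", "cvm"]
METHODS: tuple[str, ...] = ("mle", "mps", "lse", "wlse", "ad", "cvm")

_CLAMP = 1e-12  # probabilities inside logs are kept in [eps, 1-eps]
_LOG_BOUND = 12.0  # parameters confined to [e^-12, e^12] during search


@dataclass(frozen=True)
class EstimationConfig:
    """Optimiser settings shared by all six methods."""

    start: Optional[Params] = None  # None = automatic, data-driven start
    tol: float = 1e-8
    max_iter: int = 500
    multistart: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise DomainError("tol must be > 0")
        if self.multistart < 1:
            raise DomainError("multistart must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one estimation run."""

    method: str
    estimates: Params
    ses: Optional[tuple[float, float, float]]
    objective: float  # maximised log-lik / mean log-spacing, or minimised distance
    n: int
    converged: bool
    iterations: int

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "alpha": self.estimates.alpha,
            "beta": self.estimates.beta,
            "lam": self.estimates.lam,
            "objective": self.objective,
            "n": self.n,
            "converged": self.converged,
            "iterations": self.iterations,
        }
        if self.ses is not None:
            d["se_alpha"], d["se_beta"], d["se_lam"] = self.ses
        return d


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def log_likelihood(params, sample: Sample) -> float:
    """Log-likelihood of the sample, written out term by term:

    l = n ln a + n ln b - 2n ln lam + sum ln x_i - sum x_i / lam
        + (b-1) sum ln G_i - (b+1) sum ln(1-G_i) - (a+1) sum ln(1+W_i^b),

    with G the ME baseline cdf and W its odds.  Numerically identical to
    summing the log-density, but kept in this expanded form so the two code
    paths can check each other.
    """
    p = as_params(params)
    x = sample.values
    if np.any(x <= 0):
        raise DomainError("log-likelihood requires strictly positive data")
    n = x.size
    u = x / p.lam
    l1mG = np.log1p(u) - u
    G = -np.expm1(l1mG)
    lG = np.log(G)
    t = p.beta * (lG - l1mG)
    l1pwb = np.where(t > 33.0, t, np.log1p(np.exp(np.minimum(t, 33.0))))
    return float(
        n * math.log(p.alpha)
        + n * math.log(p.beta)
        - 2.0 * n * math.log(p.lam)
        + np.sum(np.log(x))
        - np.sum(x) / p.lam
        + (p.beta - 1.0) * np.sum(lG)
        - (p.beta + 1.0) * np.sum(l1mG)
        - (p.alpha + 1.0) * np.sum(l1pwb)
    )


def _mps_objective(p: Params, xs: np.ndarray) -> float:
    """Mean log-spacing with F(x_(0)) = 0 and F(x_(n+1)) = 1; zero spacings
    from ties are replaced by the log-density at the tied point (the
    Cheng-Amin adjustment)."""
    F = np.concatenate(([0.0], cdf(xs, p), [1.0]))
    d = np.diff(F)
    tied = d <= 0
    logd = np.empty_like(d)
    logd[~tied] = np.log(np.maximum(d[~tied], _CLAMP))
    if tied.any():
        # index i of spacing (x_(i-1), x_(i)); attribute ties to x_(i)
        idx = np.minimum(np.flatnonzero(tied), xs.size - 1)
        logd[tied] = logpdf(xs[idx], p)
    return float(np.mean(logd))


def objective(method: Method, params, sample: Sample) -> float:
    """Evaluate one of the six estimation criteria at given parameters.

    mle and mps are values to MAXIMISE (log-likelihood; mean log-spacing);
    lse, wlse, ad and cvm are distances to MINIMISE.
    """
    p = as_params(params)
    xs = sample.sorted_values
    n = xs.size
    i = np.arange(1, n + 1)
    if method == "mle":
        return log_likelihood(p, sample)
    if method == "mps":
        return _mps_objective(p, xs)
    F = np.clip(cdf(xs, p), _CLAMP, 1.0 - _CLAMP)
    if method == "lse":
        return float(np.sum((F - i / (n + 1.0)) ** 2))
    if method == "wlse":
        v = i * (n - i + 1.0) / ((n + 2.0) * (n + 1.0) ** 2)
        return float(np.sum((F - i / (n + 1.0)) ** 2 / v))
    if method == "ad":
        return float(
            -n - np.sum((2.0 * i - 1.0) / n * (np.log(F) + np.log1p(-F[::-1])))
        )
    if method == "cvm":
        return float(1.0 / (12.0 * n) + np.sum((F - (2.0 * i - 1.0) / (2.0 * n)) ** 2))
    raise DomainError(f"unknown estimation method {method!r}")


# ---------------------------------------------------------------------------
# gradients (complex-step: exact to machine precision, one evaluation per
# component, valid because the log-likelihood is analytic in the parameters)
# ---------------------------------------------------------------------------

def _loglik_analytic(a, b, lam, x: np.ndarray):
    """Log-likelihood written with complex-safe primitives only."""
    n = x.size
    u = x / lam
    l1mG = np.log1p(u) - u
    G = -np.expm1(l1mG)
    lG = np.log(G)
    t = b * (lG - l1mG)
    big = np.real(t) > 33.0
    l1pwb = np.where(big, t + np.log1p(np.exp(-np.where(big, t, 0.0))),
                     np.log1p(np.exp(np.where(big, 0.0, t))))
    return (
        n * np.log(a)
        + n * np.log(b)
        - 2.0 * n * np.log(lam)
        + np.sum(np.log(x))
        - np.sum(x) / lam
        + (b - 1.0) * np.sum(lG)
        - (b + 1.0) * np.sum(l1mG)
        - (a + 1.0) * np.sum(l1pwb)
    )


def _loglik_grad(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Gradient of the log-likelihood in the original parameter scale."""
    h = 1e-200
    g = np.empty(3)
    base = [complex(v) for v in params]
    for k in range(3):
        args = list(base)
        args[k] = args[k] + 1j * h
        g[k] = np.imag(_loglik_analytic(args[0], args[1], args[2], x)) / h
    return g


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _auto_start(sample: Sample) -> np.ndarray:
    """Data-driven start in log space: ME moment relation E X = 2*lam gives
    lam0 = mean/2; both shapes start at 1."""
    lam0 = float(np.mean(sample.values)) / 2.0
    return np.log(np.array([1.0, 1.0, max(lam0, 1e-6)]))


def _starts(sample: Sample, config: EstimationConfig) -> list[np.ndarray]:
    base = (
        np.log(np.asarray(as_params(config.start).as_tuple()))
        if config.start is not None
        else _auto_start(sample)
    )
    starts = [base]
    rng = np.random.default_rng(config.seed)
    for _ in range(config.multistart - 1):
        starts.append(base + rng.normal(0.0, 1.0, size=3))
    return starts


def fit(
    sample: Sample,
    method: Method = "mle",
    config: EstimationConfig | None = None,
) -> FitResult:
    """Estimate (alpha, beta, lam) by the requested criterion.

    The search runs over theta = log(alpha, beta, lam) with an L-BFGS-B
    quasi-Newton optimiser and `config.multistart` seeded starting points;
    the best local optimum is returned.  Non-convergence is flagged on the
    result, never raised.  For method="mle" the observed-information
    standard errors are attached when the Hessian is invertible.
    """
    cfg = config or EstimationConfig()
    sign = -1.0 if method in ("mle", "mps") else 1.0

    def f(theta: np.ndarray) -> float:
        p = Params(*np.exp(theta))
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = sign * objective(method, p, sample)
        return v if math.isfinite(v) else 1e300

    jac = None
    if method == "mle":
        # exact gradient (complex step), mapped to log space by the chain rule
        def jac(theta: np.ndarray) -> np.ndarray:
            v = np.exp(theta)
            with np.errstate(all="ignore"):
                g = -_loglik_grad(v, sample.values) * v
            return np.where(np.isfinite(g), g, 0.0)

    best = None
    total_iter = 0
    bounds = [(-_LOG_BOUND, _LOG_BOUND)] * 3
    for theta0 in _starts(sample, cfg):
        theta0 = np.clip(theta0, -_LOG_BOUND, _LOG_BOUND)
        # with an exact gradient the mle can afford a much tighter stop
        options = (
            {"ftol": 1e-13, "gtol": 1e-6, "maxiter": cfg.max_iter}
            if method == "mle"
            else {"ftol": cfg.tol, "gtol": 1e-8, "maxiter": cfg.max_iter}
        )
        res = optimize.minimize(
            f,
            theta0,
            jac=jac,
            method="L-BFGS-B",
            bounds=bounds,
            options=options,
        )
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res

    est = Params(*np.exp(best.x))
    # a stalled line search at an already-stationary point still counts
    converged = bool(best.success) or (
        jac is not None and np.max(np.abs(best.jac)) < 1e-5
    )
    result = FitResult(
        method=method,
        estimates=est,
        ses=None,
        objective=sign * float(best.fun),
        n=sample.n,
        converged=converged,
        iterations=total_iter,
    )
    if method == "mle" and result.converged:
        ses = standard_errors(sample, result)
        result = FitResult(**{**result.__dict__, "ses": ses})
    return result


def _hessian(grad, x0: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Numerical Hessian as central differences of a gradient function.

    Returned raw (no symmetrisation); exact arithmetic would make it
    symmetric, so the asymmetry measures the finite-difference error."""
    k = x0.size
    h = rel_step * np.abs(x0)
    H = np.empty((k, k))
    for a in range(k):
        ea = np.zeros(k)
        ea[a] = h[a]
        H[:, a] = (grad(x0 + ea) - grad(x0 - ea)) / (2.0 * h[a])
    return H


def standard_errors(sample: Sample, fitres: FitResult):
    """Observed-information standard errors at the MLE.

    Square roots of the diagonal of the inverse numerical Hessian of the
    negative log-likelihood, evaluated at the estimates in the original
    parameter scale.  The Hessian is symmetrised by averaging with its
    transpose.  Returns None (with a warning) if it is not positive
    definite / invertible.
    """
    if fitres.method != "mle":
        raise DomainError("standard errors are defined for the MLE fit only")
    x0 = np.asarray(fitres.estimates.as_tuple())
    H = _hessian(lambda v: -_loglik_grad(v, sample.values), x0)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
            raise np.linalg.LinAlgError("non-positive variance estimates")
    except np.linalg.LinAlgError as exc:
        warnings.warn(f"observed information not invertible: {exc}")
        return None
    return tuple(float(s) for s in np.sqrt(diag))
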