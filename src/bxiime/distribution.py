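"""The Burr XII-moment exponential (BXII-ME) distribution.

The moment exponential (ME, also "length-biased exponential") baseline has
density ``g(x) = x exp(-x/lam) / lam**2`` on ``x > 0``.  Feeding its odds
function ``W(x) = G(x) / (1 - G(x))`` through a Burr XII generator yields a
three-parameter lifetime law with cdf

    F(x; alpha, beta, lam) = 1 - [1 + W(x)**beta]**(-alpha),    x >= 0,

with outer shape ``alpha > 0``, inner shape ``beta > 0`` and scale
``lam > 0``.  The family contains the log-logistic-ME (``alpha = 1``), the
Lomax-ME (``beta = 1``) and the ME itself (``alpha = beta = 1``), and it is
a scale family in ``lam``.

All functions are vectorised over the observation argument.  Everything is
evaluated in log space: the literal textbook formulas overflow once
``x >> lam``, whereas ``log W`` grows only linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence, Union

import numpy as np
from scipy import special

from .exceptions import DataValidationError, DomainError

__all__ = [
    "Params",
    "Sample",
    "HazardSuite",
    "odds_me",
    "cdf",
    "sf",
    "pdf",
    "logpdf",
    "hazard_suite",
    "quantile",
    "sample",
    "log_logistic_me",
    "lomax_me",
    "moment_exponential",
]

ParamsLike = Union["Params", Sequence[float]]


@dataclass(frozen=True)
class Params:
    """Parameter triple (alpha, beta, lam) of the BXII-ME law.

    alpha : outer Burr XII shape, > 0
    beta  : inner Burr XII shape, > 0
    lam   : ME scale, > 0, in the units of the data
    """

    alpha: float
    beta: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lam"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise DomainError(
                    f"Params.{name} must be a strictly positive finite real, got {v!r}"
                )
            object.__setattr__(self, name, float(v))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.lam)


def as_params(params: ParamsLike) -> Params:
    """Coerce a Params instance or (alpha, beta, lam) triple to Params."""
    if isinstance(params, Params):
        return params
    t = tuple(params)
    if len(t) != 3:
        raise DomainError(f"expected 3 parameters (alpha, beta, lam), got {len(t)}")
    return Params(*t)


@dataclass(frozen=True)
class Sample:
    """An ordered batch of strictly positive lifetimes."""

    values: np.ndarray
    _sorted: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 1:
            raise DataValidationError("a Sample needs at least one observation")
        if not np.all(np.isfinite(v)):
            raise DataValidationError("sample contains non-finite values")
        if np.any(v <= 0):
            bad = np.flatnonzero(v <= 0)[:5]
            raise DataValidationError(
                f"sample values must be > 0; offending indices {bad.tolist()} "
                f"with values {v[bad].tolist()}"
            )
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "_sorted", np.sort(v))

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def sorted_values(self) -> np.ndarray:
        """Order statistics x_(1) <= ... <= x_(n)."""
        return self._sorted

    @classmethod
    def from_iterable(cls, values: Iterable[float]) -> "Sample":
        return cls(np.fromiter(values, dtype=float))


class HazardSuite(NamedTuple):
    """Survival-analysis functionals of the BXII-ME law at a point."""

    sf: np.ndarray
    hazard: np.ndarray
    cum_hazard: np.ndarray
    rev_hazard: np.ndarray
    elasticity: np.ndarray


# ---------------------------------------------------------------------------
# stable building blocks
# ---------------------------------------------------------------------------

def _check_x(x, allow_zero: bool = True) -> np.ndarray:
    xa = np.asarray(x, dtype=float)
    if np.any(np.isnan(xa)):
        raise DomainError("x must not be NaN")
    return xa


def _log_sf_me(x: np.ndarray, lam: float) -> np.ndarray:
    """log(1 - G(x)) = log1p(x/lam) - x/lam for the ME baseline."""
    u = x / lam
    return np.log1p(u) - u


def _log_G_and_log1mG(x: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    l1mG = _log_sf_me(x, lam)
    G = -np.expm1(l1mG)
    with np.errstate(divide="ignore"):
        lG = np.log(G)
    return lG, l1mG


def _log1p_exp(t: np.ndarray) -> np.ndarray:
    """log(1 + exp(t)), stable for large |t|."""
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    big = t > 33.0
    out[big] = t[big]
    small = t < -33.0
    out[small] = np.exp(t[small])
    mid = ~(big | small)
    out[mid] = np.log1p(np.exp(t[mid]))
    return out


def _log1p_wbeta(x: np.ndarray, p: Params) -> np.ndarray:
    """log(1 + W(x)**beta) evaluated without forming W**beta."""
    lG, l1mG = _log_G_and_log1mG(x, p.lam)
    with np.errstate(invalid="ignore"):
        t = p.beta * (lG - l1mG)
    return _log1p_exp(np.where(x > 0, t, -np.inf))


# ---------------------------------------------------------------------------
# public distribution functions
# ---------------------------------------------------------------------------

def odds_me(x, lam: float):
    """Odds W(G(x)) = G/(1-G) of the ME baseline cdf.

    Strictly increasing from 0 at x = 0, diverging as x -> inf, with leading
    order (x/lam)**2 / 2 near the origin.
    """
    if not (lam > 0 and math.isfinite(lam)):
        raise DomainError(f"lam must be > 0, got {lam!r}")
    xa = _check_x(x)
    if np.any(xa < 0):
        raise DomainError("odds_me requires x >= 0")
    lG, l1mG = _log_G_and_log1mG(xa, lam)
    with np.errstate(invalid="ignore", over="ignore"):
        w = np.exp(lG - l1mG)
    w = np.where(xa == 0, 0.0, w)
    return w if w.ndim else float(w)


def log_sf(x, params: ParamsLike):
    """log S(x) = -alpha * log(1 + W**beta); 0 for x <= 0."""
    p = as_params(params)
    xa = _check_x(x)
    out = -p.alpha * _log1p_wbeta(np.maximum(xa, 0.0), p)
    out = np.where(xa <= 0, 0.0, out)
    return out if out.ndim else float(out)


def sf(x, params: ParamsLike):
    """Survival function S(x) = {1 + W(x)**beta}**(-alpha)."""
    out = np.exp(log_sf(x, params))
    return out if np.ndim(out) else float(out)


def cdf(x, params: ParamsLike):
    """Distribution function F(x) = 1 - {1 + W(x)**beta}**(-alpha)."""
    out = -np.expm1(log_sf(x, params)) + 0.0  # +0.0 normalises -0.0 at x <= 0
    return out if np.ndim(out) else float(out)


def logpdf(x, params: ParamsLike):
    """Log-density; -inf outside the support (x <= 0).

    ln f = ln(alpha*beta) + ln x - 2 ln lam - x/lam
           + (beta-1) ln G - (beta+1) ln(1-G) - (alpha+1) ln(1 + W**beta).
    """
    p = as_params(params)
    xa = _check_x(x)
    xpos = np.where(xa > 0, xa, 1.0)  # placeholder off-support
    lG, l1mG = _log_G_and_log1mG(xpos, p.lam)
    l1pwb = _log1p_exp(p.beta * (lG - l1mG))
    out = (
        math.log(p.alpha)
        + math.log(p.beta)
        + np.log(xpos)
        - 2.0 * math.log(p.lam)
        - xpos / p.lam
        + (p.beta - 1.0) * lG
        - (p.beta + 1.0) * l1mG
        - (p.alpha + 1.0) * l1pwb
    )
    out = np.where(xa > 0, out, -np.inf)
    return out if out.ndim else float(out)


def pdf(x, params: ParamsLike):
    """Density of the BXII-ME law; 0 for x <= 0."""
    with np.errstate(over="ignore"):
        out = np.exp(logpdf(x, params))
    return out if np.ndim(out) else float(out)


def hazard_suite(x, params: ParamsLike) -> HazardSuite:
    """Survival function, hazard, cumulative hazard, reversed hazard and
    elasticity at x > 0.

    hazard = f/S, cum_hazard = alpha*ln(1 + W**beta) = -ln S,
    rev_hazard = f/F, elasticity = d ln F / d ln x = x*f/F.
    """
    p = as_params(params)
    xa = _check_x(x)
    if np.any(xa <= 0):
        raise DomainError("hazard_suite requires x > 0")
    ls = np.asarray(log_sf(xa, p))
    lf = np.asarray(logpdf(xa, p))
    F = -np.expm1(ls)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        haz = np.exp(lf - ls)
        rev = np.exp(lf) / F
    return HazardSuite(
        sf=np.exp(ls), hazard=haz, cum_hazard=-ls, rev_hazard=rev,
        elasticity=xa * rev,
    )


def _x_from_log1pT(log1pT, lam: float):
    """Solve (1 + u) e^{-u} = 1/(1+T) for u >= 0 given t = log(1+T), and
    return x = lam * u.

    The lower Lambert-W branch gives the starting point, but it loses
    accuracy near its branch point (t -> 0), so the root of the
    well-conditioned form  u - log1p(u) = t  is then polished by Newton
    steps; the equation is convex in u, so the iteration is monotone and
    safe from either side."""
    t = np.asarray(log1pT, dtype=float)
    c = np.exp(-t)
    arg = np.clip(-c / math.e, -1.0 / math.e + 1e-16, -1e-300)
    u = -1.0 - np.real(special.lambertw(arg, k=-1))
    # near the branch point the expansion u ~ sqrt(2t) is the better start
    u = np.maximum(u, np.sqrt(2.0 * t))
    with np.errstate(invalid="ignore", divide="ignore"):
        for _ in range(8):
            r = np.log1p(u) - u + t  # residual; d(r)/du = -u/(1+u)
            step = r * (1.0 + u) / np.where(u > 0, u, 1.0)
            u = np.maximum(u + np.where(u > 0, step, 0.0), 0.0)
    return lam * u


def quantile(q, params: ParamsLike):
    """Quantile function x_q with F(x_q) = q, for 0 <= q < 1.

    Closed form via the lower real branch of the Lambert W function:
    with T = [(1-q)^{-1/alpha} - 1]^{1/beta},
    x_q = -lam * (1 + W_{-1}(-1 / (e*(1+T)))),
    polished by Newton steps on the well-conditioned form of the same
    equation (the raw closed form loses precision for q near 0 or 1).
    """
    p = as_params(params)
    qa = np.asarray(q, dtype=float)
    if np.any(np.isnan(qa)) or np.any(qa < 0) or np.any(qa >= 1):
        raise DomainError("quantile requires 0 <= q < 1")
    # log(1+T) = (1/beta) * log( (1-q)^{-1/alpha} - 1 ) fed through log1p:
    with np.errstate(divide="ignore"):
        logT = np.log(np.expm1(-np.log1p(-qa) / p.alpha)) / p.beta
    log1pT = _log1p_exp(logT)
    x = _x_from_log1pT(log1pT, p.lam)
    x = np.where(qa <= 0, 0.0, x)
    return x if x.ndim else float(x)


def sample(
    n: int,
    params: ParamsLike,
    seed: int | np.random.Generator | None = None,
    method: Literal["inverse", "gamma_exp"] = "inverse",
) -> Sample:
    """Draw n i.i.d. BXII-ME variates.

    method="inverse" pushes uniforms through the Lambert-W quantile (the
    default).  method="gamma_exp" uses the gamma-exponential construction:
    with W1 ~ Exp(1) and W2 ~ Gamma(alpha, 1) independent, the solution of
    W(x)**beta = W1/W2 has the BXII-ME law.  Both target the same
    distribution; the second is kept as a cross-validation sampler.
    """
    p = as_params(params)
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise DomainError(f"n must be an integer >= 1, got {n!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "inverse":
        u = rng.random(n)
        x = quantile(u, p)
    elif method == "gamma_exp":
        w1 = rng.standard_exponential(n)
        w2 = rng.standard_gamma(p.alpha, n)
        # W**beta = w1/w2  =>  log(1+T) with T = (w1/w2)**(1/beta)
        logT = (np.log(w1) - np.log(w2)) / p.beta
        x = _x_from_log1pT(_log1p_exp(logT), p.lam)
    else:
        raise DomainError(f"unknown sampling method {method!r}")
    return Sample(np.atleast_1d(x))


# ---------------------------------------------------------------------------
# named sub-models
# ---------------------------------------------------------------------------

def log_logistic_me(beta: float, lam: float) -> Params:
    """Log-logistic-ME sub-model (alpha = 1)."""
    return Params(1.0, beta, lam)


def lomax_me(alpha: float, lam: float) -> Params:
    """Lomax-ME sub-model (beta = 1); S(x) = [(1+x/lam)e^{-x/lam}]**alpha."""
    return Params(alpha, 1.0, lam)


def moment_exponential(lam: float) -> Params:
    """The ME baseline itself (alpha = beta = 1)."""
    return Params(1.0, 1.0, lam)
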