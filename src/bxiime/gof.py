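"""Model-selection criteria and goodness-of-fit statistics.

Information criteria take the fitted -2*loglik directly; the distance
statistics (Cramer-von Mises W*, Anderson-Darling A*, Kolmogorov-Smirnov)
are computed on the probability-integral transforms u_i = F(x_(i)) of the
ordered sample under the candidate parameters, with the Chen-Balakrishnan
small-sample modification factors.  The total-time-on-test (TTT) transform
is included as the standard hazard-shape diagnostic (a concave TTT curve
indicates an increasing failure rate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .distribution import ParamsLike, Sample, as_params, cdf
from .estimation import log_likelihood
from .exceptions import DomainError

__all__ = [
    "InformationCriteria",
    "GofStatistics",
    "GofReport",
    "information_criteria",
    "gof_statistics",
    "gof_report",
    "ttt_points",
]

_CLAMP = 1e-12


@dataclass(frozen=True)
class InformationCriteria:
    aic: float
    caic: float
    bic: float
    hqic: float


@dataclass(frozen=True)
class GofStatistics:
    wstar: float
    astar: float
    ks_stat: float
    ks_pvalue: float


@dataclass(frozen=True)
class GofReport:
    neg2ll: float
    aic: float
    caic: float
    bic: float
    hqic: float
    wstar: float
    astar: float
    ks_stat: float
    ks_pvalue: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def information_criteria(neg2ll: float, k: int, n: int) -> InformationCriteria:
    """AIC, corrected AIC, BIC and HQIC from a fitted -2*loglik.

    AIC  = -2l + 2k
    CAIC = AIC + 2k(k+1)/(n-k-1)
    BIC  = -2l + k ln n
    HQIC = -2l + 2k ln(ln n)
    """
    if not n > k + 1:
        raise DomainError(f"need n > k+1 for the corrected AIC (n={n}, k={k})")
    aic = neg2ll + 2.0 * k
    return InformationCriteria(
        aic=aic,
        caic=aic + 2.0 * k * (k + 1.0) / (n - k - 1.0),
        bic=neg2ll + k * math.log(n),
        hqic=neg2ll + 2.0 * k * math.log(math.log(n)),
    )


def _kolmogorov_pvalue(n: int, d: float) -> float:
    """Asymptotic Kolmogorov p-value 2*sum (-1)^(j-1) exp(-2 j^2 n d^2)."""
    return float(special.kolmogorov(math.sqrt(n) * d))


def gof_statistics(sample: Sample, params: ParamsLike) -> GofStatistics:
    """W*, A*, and the K-S statistic with its asymptotic p-value.

    On u_i = F(x_(i)):
    W2 = 1/(12n) + sum (u_i - (2i-1)/(2n))^2,   W* = W2 (1 + 0.5/n)
    A2 = -n - (1/n) sum (2i-1)[ln u_i + ln(1-u_{n+1-i})],
                                                A* = A2 (1 + 0.75/n + 2.25/n^2)
    KS = max_i max(i/n - u_i, u_i - (i-1)/n), p from the Kolmogorov series.
    """
    p = as_params(params)
    xs = sample.sorted_values
    n = xs.size
    if n < 2:
        raise DomainError("goodness-of-fit statistics need n >= 2")
    u = np.asarray(cdf(xs, p))
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        warnings.warn("probability transforms at 0 or 1 were clamped")
        u = np.clip(u, _CLAMP, 1.0 - _CLAMP)
    i = np.arange(1, n + 1)
    w2 = 1.0 / (12.0 * n) + np.sum((u - (2.0 * i - 1.0) / (2.0 * n)) ** 2)
    a2 = -n - np.sum((2.0 * i - 1.0) * (np.log(u) + np.log1p(-u[::-1]))) / n
    ks = float(max(np.max(i / n - u), np.max(u - (i - 1.0) / n)))
    return GofStatistics(
        wstar=float(w2 * (1.0 + 0.5 / n)),
        astar=float(a2 * (1.0 + 0.75 / n + 2.25 / n**2)),
        ks_stat=ks,
        ks_pvalue=_kolmogorov_pvalue(n, ks),
    )


def gof_report(sample: Sample, params: ParamsLike, k: int = 3) -> GofReport:
    """Full report: -2*loglik, four information criteria and the three
    distance statistics, for a BXII-ME fit with k estimated parameters."""
    p = as_params(params)
    neg2ll = -2.0 * log_likelihood(p, sample)
    ic = information_criteria(neg2ll, k, sample.n)
    gs = gof_statistics(sample, p)
    return GofReport(
        neg2ll=neg2ll,
        aic=ic.aic, caic=ic.caic, bic=ic.bic, hqic=ic.hqic,
        wstar=gs.wstar, astar=gs.astar,
        ks_stat=gs.ks_stat, ks_pvalue=gs.ks_pvalue,
    )


def ttt_points(sample: Sample) -> np.ndarray:
    """Scaled total-time-on-test transform.

    Returns an (n, 2) array of pairs (i/n, T_i) with
    T_i = [sum_{j<=i} x_(j) + (n-i) x_(i)] / sum_j x_(j); T_n = 1.
    """
    xs = sample.sorted_values
    n = xs.size
    if n < 2:
        raise DomainError("the TTT transform needs n >= 2")
    i = np.arange(1, n + 1)
    csum = np.cumsum(xs)
    T = (csum + (n - i) * xs) / csum[-1]
    return np.column_stack((i / n, T))
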