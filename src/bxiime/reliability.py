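"""Multicomponent stress-strength reliability.

A system of kappa identical components works while at least s of them
withstand a common random stress.  With strengths X_i ~ BXII-ME(alpha1,
beta, lam) i.i.d. and stress Y ~ BXII-ME(alpha2, beta, lam) independent of
them, the system reliability has the closed form

    R_{s,kappa} = (1/nu) * sum_{l=s}^{kappa} C(kappa, l) B(l + 1/nu, kappa - l + 1),

with nu = alpha1/alpha2 and B the beta function.  The shared beta and lam
cancel, so R depends on the shapes only through nu.  For s = kappa = 1 it
reduces to the classical stress-strength probability
P(Y < X) = alpha2/(alpha1 + alpha2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import special

from .exceptions import DomainError

__all__ = ["StressStrengthSpec", "multicomponent_reliability"]


@dataclass(frozen=True)
class StressStrengthSpec:
    """s-out-of-kappa stress-strength system with BXII-ME strengths/stress."""

    s: int
    kappa: int
    alpha1: float  # strength outer shape
    alpha2: float  # stress outer shape

    def __post_init__(self) -> None:
        if not (isinstance(self.s, int) and isinstance(self.kappa, int)):
            raise DomainError("s and kappa must be integers")
        if not (1 <= self.s <= self.kappa):
            raise DomainError(f"need 1 <= s <= kappa, got s={self.s}, kappa={self.kappa}")
        if not (self.alpha1 > 0 and self.alpha2 > 0):
            raise DomainError("alpha1 and alpha2 must be > 0")


def multicomponent_reliability(spec: StressStrengthSpec) -> float:
    """R_{s,kappa}: probability that at least s of kappa strengths exceed
    the stress.  Evaluated with log-binomial + log-beta terms for stability
    up to kappa ~ 1e3."""
    nu = spec.alpha1 / spec.alpha2
    terms = [
        math.exp(
            _log_comb(spec.kappa, l)
            + special.betaln(l + 1.0 / nu, spec.kappa - l + 1.0)
        )
        for l in range(spec.s, spec.kappa + 1)
    ]
    return math.fsum(terms) / nu


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
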