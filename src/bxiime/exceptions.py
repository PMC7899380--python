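"""Exception hierarchy for bxiime."""


class BxiimeError(Exception):
    """Base class for all package errors."""


class DomainError(BxiimeError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DataValidationError(BxiimeError, ValueError):
    """Input data violate a contract (non-positive lifetimes, parse failures)."""


class NumericalError(BxiimeError, RuntimeError):
    """A numerical routine (quadrature, linear algebra) failed to converge."""
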