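"""Shared exception and warning types."""


class ToxvarError(Exception):
    """Base class for package errors."""


class DomainError(ToxvarError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class DataError(ToxvarError, ValueError):
    """Input tables are missing, malformed, or degenerate beyond use."""


class FitError(ToxvarError, RuntimeError):
    """A model fit cannot proceed (too few points, rank deficiency, ...)."""


class ExtrapolationError(ToxvarError, ValueError):
    """A dose distribution lies outside a fitted curve's dose range."""


class NonDifferentiableCurveError(ToxvarError, TypeError):
    """Second derivative requested for a curve form that has none."""


class ExtrapolationWarning(UserWarning):
    """A smooth curve was evaluated beyond its fitted dose range."""


class DegenerateDataWarning(UserWarning):
    """Data were degenerate and a documented fallback was used."""
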