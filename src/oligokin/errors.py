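"""Typed exceptions and warnings shared across the package.

Every failure mode that a caller can reasonably handle gets its own
exception class; nothing is ever swallowed silently.
"""

from __future__ import annotations


class OligokinError(Exception):
    """Base class for all package errors."""


class ParameterError(OligokinError, ValueError):
    """A physical parameter is outside its admissible range."""


class IntegrationError(OligokinError, RuntimeError):
    """ODE integration failed or produced unphysical values."""


class NoPlateauError(OligokinError, ValueError):
    """A kinetic trace has not reached its final plateau."""


class NoCrossingError(OligokinError, ValueError):
    """A normalized trace never crosses the half-conversion level."""


class FitFailureError(OligokinError, RuntimeError):
    """Nonlinear optimization failed to converge.

    Carries the best point found so far in ``best`` (may be None).
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class CalibrationError(OligokinError, ValueError):
    """Channel calibration is impossible (anchor outside physical range)."""


class OutOfRangeError(OligokinError, ValueError):
    """A diffused fraction is outside the invertible range of the
    forward map — the instrument's "size determination not possible"
    condition."""


class MixtureError(OligokinError, ValueError):
    """Species mixture is invalid (fractions do not sum to one, ...)."""


class ConfigError(OligokinError, ValueError):
    """Unknown scenario or inconsistent run configuration."""


class ParseError(OligokinError, ValueError):
    """A data file does not conform to its documented dialect."""


class QCWarning(UserWarning):
    """Non-fatal quality-control condition (e.g. diffused fraction
    marginally above 0.5 clipped to the physical range)."""
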