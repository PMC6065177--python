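"""Exception hierarchy shared across the package.

Every error a caller may want to catch selectively gets its own class;
all inherit from :class:`PhasorfoldError`.
"""


class PhasorfoldError(Exception):
    """Base class for all package errors."""


# --- I/O -----------------------------------------------------------------

class SpectraIOError(PhasorfoldError):
    """Base class for file reading/writing errors."""


class FormatError(SpectraIOError):
    """A required column or field is missing, or the layout is wrong."""


class ParseError(SpectraIOError):
    """A cell could not be converted to a number; message names the row."""


class IntegrityError(SpectraIOError):
    """Duplicate or mutually inconsistent records in an input file."""


class ReportError(SpectraIOError):
    """A fit report cannot be written (e.g. fit did not converge)."""


# --- domain validation ----------------------------------------------------

class ValidationError(PhasorfoldError):
    """A domain object violates one of its invariants."""


class ConfigError(PhasorfoldError):
    """A simulation or pipeline configuration is invalid."""


# --- observables / phasor -------------------------------------------------

class UndefinedObservableError(PhasorfoldError):
    """Observable undefined, e.g. center of mass of an all-zero spectrum."""


class DegenerateEndpointsError(PhasorfoldError):
    """Folded/unfolded endpoint values coincide; normalization impossible."""


class EmptyWindowError(PhasorfoldError):
    """An integration window contains no spectral samples."""


class UndefinedPhasorError(PhasorfoldError):
    """Phasor of a spectrum with zero total intensity."""


class DegenerateLineError(PhasorfoldError):
    """Endpoint phasors coincide; no linear-combination line exists."""


# --- fitting --------------------------------------------------------------

class InsufficientDataError(PhasorfoldError):
    """Too few usable points for the requested fit."""


class DomainError(PhasorfoldError):
    """Argument outside the mathematical domain of an operation."""


class FitFailureError(PhasorfoldError):
    """Nonlinear fit failed to converge from every starting point."""


class UndefinedLagError(PhasorfoldError):
    """Lag time undefined (zero-amplitude kinetic fit)."""


class FlatCurveError(PhasorfoldError):
    """A transition curve has no derivative maximum (flat)."""


# --- warnings -------------------------------------------------------------

class OutOfRangeAlphaWarning(UserWarning):
    """Fraction unfolded outside [0, 1]; kept unclipped, caller is warned."""


class NonUnimodalDerivativeWarning(UserWarning):
    """Derivative of a transition curve has multiple local maxima."""


class DegenerateFitWarning(UserWarning):
    """Regression slope is (numerically) zero; parameters set accordingly."""
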