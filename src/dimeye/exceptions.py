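"""Exception hierarchy shared across the package.

All domain-violating inputs raise :class:`DomainError` (a ``ValueError``),
so callers can distinguish "your number is physically impossible" from
estimation failures on valid but uninformative data.
"""


class DimeyeError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DimeyeError, ValueError):
    """An input is outside the physically meaningful domain of an operation."""


class EstimationError(DimeyeError):
    """Valid inputs, but no estimate can be formed (e.g. flat focus series)."""


class InsufficientDataError(EstimationError):
    """Too few usable data points for the requested estimate."""


class NoCutoffError(EstimationError):
    """Contrast does not decrease with spatial frequency; no x-intercept."""


class FitError(EstimationError):
    """Template fit failed (flat/monotone spectrum, no interior optimum)."""


class NoCrossingError(EstimationError):
    """Requested sensitivity level is not attained on the requested limb."""


class GridMismatchError(DimeyeError, ValueError):
    """Two spectra do not share (or overlap) a common wavelength grid."""


class ParseError(DimeyeError, ValueError):
    """A data file is malformed; the message names the offending line."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class BoundaryWarning(UserWarning):
    """An optimum/maximum sits at the edge of the measured range."""


class UnreliableCIWarning(UserWarning):
    """More than 10% of bootstrap replicates failed to fit."""
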