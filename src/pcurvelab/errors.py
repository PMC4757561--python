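"""Exception hierarchy used across the package."""

from __future__ import annotations


class PCurveLabError(Exception):
    """Base class for all pcurvelab errors."""


class InvalidParameterError(PCurveLabError, ValueError):
    """A parameter lies outside its documented domain."""


class NoSolutionError(PCurveLabError, ValueError):
    """A calibration equation has no solution in the admissible range."""


class DegenerateSampleError(PCurveLabError, ValueError):
    """The sample is too small to fit the requested model."""


class CollinearityError(PCurveLabError, ValueError):
    """The design matrix is rank deficient or numerically singular.

    ``columns`` names the offending columns when they could be identified.
    """

    def __init__(self, message: str, columns: tuple[str, ...] = ()) -> None:
        super().__init__(message)
        self.columns = tuple(columns)


class EmptyInputError(PCurveLabError, ValueError):
    """An operation received an empty collection."""


class UndefinedSkewError(PCurveLabError, ValueError):
    """Skew direction is undefined (no significant p-values to bin)."""


class SchemaError(PCurveLabError, ValueError):
    """An input file does not expose the expected columns."""


class InsufficientDataError(PCurveLabError, ValueError):
    """Too few complete rows remain after filtering."""


class SearchExhaustedError(PCurveLabError, RuntimeError):
    """The specification search hit its attempt bound before harvesting
    the requested number of estimates.  ``hits`` carries the partial yield."""

    def __init__(self, message: str, hits=None) -> None:
        super().__init__(message)
        self.hits = hits
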