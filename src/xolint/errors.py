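"""Exception hierarchy shared across the package."""


class XolintError(Exception):
    """Base class for all package-specific errors."""


class FormatError(XolintError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(XolintError):
    """Data violates a domain invariant (e.g. position outside [0, L])."""


class MissingLengthError(XolintError, KeyError):
    """A chromosome length required for the operation is unavailable."""


class DegenerateDataError(XolintError):
    """The estimator is undefined on this input (e.g. no crossovers at all)."""


class InsufficientDataError(XolintError):
    """Too few observations for a stable fit."""


class ParameterError(XolintError, ValueError):
    """An argument is outside its allowed range."""


class ResamplingError(XolintError):
    """Resampling could not produce enough non-degenerate replicates."""


class ClusteringWarning(UserWarning):
    """Observed pair count exceeds the Poisson-null expectation.

    Emitted when the missing-pair count is negative, i.e. crossovers are
    clustered relative to independent placement (negative interference).
    The interference length is still reported and may be negative.
    """
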