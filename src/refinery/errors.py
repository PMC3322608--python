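"""Exception types shared across the package."""


class RefineryError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(RefineryError, ValueError):
    """A precondition on an operation's input was violated."""


class EmptyDatasetError(RefineryError):
    """Sanitation rejected every reflection in the data set."""


class EmptyModelError(RefineryError):
    """Stripping removed every atom from the model."""


class UndefinedZError(RefineryError):
    """Z(R_free) cannot be computed (sigma = 0 or R_ratio unavailable).

    Callers are expected to fall back to gap-based tests (see bselect and
    picker) rather than treat this as fatal.
    """


class UndefinedFitError(RefineryError):
    """No map grid point falls within any atom's radius."""


class PipelineAbort(RefineryError):
    """The pipeline stopped prematurely; ``status`` names the abort rule."""

    def __init__(self, status: str, message: str = ""):
        super().__init__(message or status)
        self.status = status
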