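"""Exception hierarchy shared across the package."""


class DPRError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DPRError, ValueError):
    """A parameter is outside its admissible range."""


class TruncationError(InvalidParameterError):
    """Stick proportions violate the truncation convention (last stick != 1)."""


class DegenerateDataError(DPRError, ValueError):
    """Input data carry no usable signal (e.g. all values identical)."""


class FormatError(DPRError, ValueError):
    """A genotype/phenotype file violates its declared on-disk format."""


class EmptyPanelError(DPRError, ValueError):
    """Quality control removed every SNP."""


class DivergenceError(DPRError, RuntimeError):
    """Non-finite values appeared during inference."""


class InternalConsistencyError(DPRError, RuntimeError):
    """An internal invariant (e.g. the cached residual) was violated."""


class DegeneratePredictionWarning(UserWarning):
    """Predictions are constant; the squared correlation is reported as 0."""
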