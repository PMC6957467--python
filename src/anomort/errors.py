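"""Exception types shared across the package."""


class AnomortError(Exception):
    """Base class for all package errors."""


class ValidationError(AnomortError):
    """Structured input-validation failure.

    Parameters
    ----------
    message : str
        Human-readable description.
    gaps : list, optional
        The offending records/combinations, kept machine-readable so callers
        can report or repair them.
    """

    def __init__(self, message, gaps=None):
        super().__init__(message)
        self.gaps = list(gaps) if gaps is not None else []


class ConvergenceError(AnomortError):
    """Raised when a model fit fails its convergence diagnostics."""
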