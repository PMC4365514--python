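"""Exception hierarchy shared across the pipeline."""


class AeroPhenoError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(AeroPhenoError):
    """A sensor specification or argument violates its invariants."""


class RegistrationInfeasibleError(AeroPhenoError):
    """Fewer than four markers were found; carries the partial detections.

    Mirrors the manual-override path of the field workflow: the caller may
    supply hand-picked marker centres and retry.
    """

    def __init__(self, message, detections=None):
        super().__init__(message)
        self.detections = list(detections) if detections is not None else []


class UndefinedCorrelationError(AeroPhenoError):
    """Zero-variance input makes a correlation score undefined."""


class FitError(AeroPhenoError):
    """A projective fit failed (too few or degenerate correspondences)."""


class ConfigurationError(AeroPhenoError):
    """A run configuration is missing or invalid."""


class DataError(AeroPhenoError):
    """Input data violates a stated precondition (e.g. t_max < t_min)."""


class UndefinedSkewnessError(AeroPhenoError):
    """Skewness is undefined for a zero-variance sample."""


class UnbalancedDesignError(AeroPhenoError):
    """The trait table is not a balanced genotype x block layout."""


class InsufficientReplicationError(AeroPhenoError):
    """Fewer than two blocks: no residual to test against."""
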