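"""Exception hierarchy for semlrt."""


class SemlrtError(Exception):
    """Base class for all semlrt errors."""


class InvalidModelError(SemlrtError):
    """A population or analysis model violates its constraints
    (e.g. a communality >= 1 would imply a non-positive residual variance)."""


class EstimationError(SemlrtError):
    """Maximum-likelihood estimation failed to converge."""


class InfeasibleTargetError(SemlrtError):
    """A moment target cannot be reached with the given mixture components.

    Carries the achievable range so callers can report diagnostics.
    """

    def __init__(self, message, achievable_range=None):
        super().__init__(message)
        self.achievable_range = achievable_range


class CalibrationError(SemlrtError):
    """NORTA / Vale-Maurelli intermediate-correlation calibration failed."""
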