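"""Exception hierarchy for adpois."""


class AdpoisError(Exception):
    """Base class for all adpois errors."""


class ValidationError(AdpoisError, ValueError):
    """Malformed input data (bad counts, gaps in visits, shape mismatch)."""


class ConstraintError(AdpoisError, ValueError):
    """Parameter values violate the model's validity constraints."""


class InfeasiblePointError(AdpoisError, ValueError):
    """Likelihood (or gradient) requested at a point where some
    conditional mean is non-positive."""


class FitError(AdpoisError, RuntimeError):
    """Model fitting failed (singular design, no feasible start, ...)."""


class SingularInformationError(FitError):
    """Observed information matrix is not invertible at the optimum."""
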