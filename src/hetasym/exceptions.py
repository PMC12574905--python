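"""Exception hierarchy shared across the package."""


class HetasymError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HetasymError, ValueError):
    """Input data violates a structural contract (shape, sign, NaN...)."""


class CalibrationError(HetasymError, RuntimeError):
    """An iterative calibration failed to reach its target."""

    def __init__(self, msg, best=None):
        super().__init__(msg)
        self.best = best


class ConvergenceError(HetasymError, RuntimeError):
    """A solver did not converge; carries the last residual when known."""

    def __init__(self, msg, residual=None):
        super().__init__(msg)
        self.residual = residual


class IdentifiabilityError(HetasymError, ValueError):
    """The separation problem is rank deficient / not identifiable."""


class StabilityError(HetasymError, ValueError):
    """A Jacobian required to be Hurwitz-stable is not."""


class BranchCutError(HetasymError, ValueError):
    """Principal matrix logarithm undefined (eigenvalue on the branch cut)."""


class IntegrationError(HetasymError, RuntimeError):
    """Stochastic integration diverged from the admissible state band."""
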