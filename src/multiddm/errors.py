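"""Exception hierarchy for multiddm."""


class MultiDDMError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MultiDDMError):
    """Invalid or inconsistent model/design configuration."""


class SolverError(MultiDDMError):
    """Numerical failure of the first-passage-time solver (e.g. mass defect)."""


class FitError(MultiDDMError):
    """All restarts of a maximum-likelihood fit failed."""


class OptimizationError(MultiDDMError):
    """No restart of the reward-rate maximization converged."""


class ProjectionError(MultiDDMError):
    """No iso-reward intersection with the optimal-bound ray on the selected branch."""


class InstabilityError(MultiDDMError):
    """Learning-rule trajectory diverged; a smaller step size is needed."""


class NumericalError(MultiDDMError):
    """Non-finite values encountered in a numerical routine."""
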