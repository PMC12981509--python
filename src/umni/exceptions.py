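"""Exception hierarchy shared across the package."""


class UmniError(Exception):
    """Base class for all package-specific errors."""


class RegistryError(UmniError):
    """Malformed disease registry input (bad CURIE, duplicate id, bad dialect)."""


class GridMismatchError(UmniError):
    """Two score matrices do not share the same disease x criterion grid."""


class RubricError(UmniError):
    """Rubric configuration problem or attribute outside the rubric domain."""


class PromptError(UmniError):
    """Unresolved placeholder or otherwise unrenderable prompt template."""


class ConfigError(UmniError):
    """Invalid rater / run configuration."""


class DegenerateDataError(UmniError):
    """Input is degenerate for the requested statistic (constant column,
    zero variance, all-zero differences...)."""


class ConvergenceError(UmniError):
    """Iterative fit failed to converge within the iteration budget."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter


class MediationError(UmniError):
    """Mediator matrix is missing a required cell or breaks the
    within-one-point-of-a-rater consensus guarantee."""
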