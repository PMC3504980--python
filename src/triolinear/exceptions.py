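"""Exception and warning types."""


class TriolinearError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TriolinearError, ValueError):
    """Invalid model, population, or scenario configuration."""


class MendelianError(TriolinearError, ValueError):
    """Genotypes inconsistent with Mendelian transmission."""


class IdentifiabilityError(TriolinearError, ValueError):
    """Design matrix is rank deficient; names the aliased parameters."""

    def __init__(self, aliased, message=None):
        self.aliased = tuple(aliased)
        if message is None:
            message = "model not identifiable; aliased parameters: " + ", ".join(self.aliased)
        super().__init__(message)


class ConvergenceError(TriolinearError, RuntimeError):
    """Optimization failed to converge."""


class DataError(TriolinearError, ValueError):
    """Malformed or internally inconsistent input data."""


class AliasingWarning(UserWarning):
    """Parameters with no informative cells were dropped from a fit."""


class FrequencyWarning(UserWarning):
    """A test result depends on user-specified genotype frequencies."""


class NonConvergenceWarning(UserWarning):
    """A fit stopped at the iteration limit without meeting tolerances."""
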