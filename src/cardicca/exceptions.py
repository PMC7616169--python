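"""Exception hierarchy used across the package."""


class CardiccaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CardiccaError, ValueError):
    """A configuration object violates its invariants."""


class ValidationError(CardiccaError, ValueError):
    """Input data violate an operation's preconditions."""


class SingularityError(CardiccaError, RuntimeError):
    """A covariance block is rank deficient and no regularization was supplied."""


class UndefinedMetricError(CardiccaError, ValueError):
    """A classification metric is requested for an empty class."""


class DivergenceError(CardiccaError, RuntimeError):
    """Optimization produced a non-finite objective."""


class StageOrderError(CardiccaError, RuntimeError):
    """A pipeline stage was requested before its prerequisites exist."""


class StratificationError(CardiccaError, ValueError):
    """A cross-validation fold cannot contain both classes."""
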