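"""Exception hierarchy shared across the package."""


class PhenoselectError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(PhenoselectError):
    """Raised when a trial design request cannot be laid out."""


class ConfigError(PhenoselectError):
    """Raised for invalid parameter / configuration combinations."""


class SingularityError(PhenoselectError):
    """Raised when a fixed-effects design is singular or a system is
    numerically rank deficient (condition number above threshold)."""


class ConvergenceError(PhenoselectError):
    """Raised when an iterative fit fails to converge and no usable
    fallback exists."""


class DegenerateModelError(PhenoselectError):
    """Raised when a model cannot be estimated (e.g. zero-variance
    response where an estimate is required)."""


class UndefinedHeritabilityError(PhenoselectError):
    """Raised when Cullis heritability is requested with zero genotype
    variance."""
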