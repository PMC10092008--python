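"""Exception taxonomy shared across the pipeline."""


class CamoquantError(Exception):
    """Base class for all package-specific errors."""


class RangeError(CamoquantError, ValueError):
    """Requested wavelengths fall outside a spectrum's support."""


class DomainError(CamoquantError, ValueError):
    """Numerical input outside the mathematical domain of an operation."""


class DegenerateCatchError(DomainError):
    """A receptor quantum catch is zero or negative; log-contrast models
    are undefined there."""


class DimensionError(CamoquantError, ValueError):
    """Array or matrix shapes are incompatible."""


class UsageError(CamoquantError, ValueError):
    """The operation was called in a way its contract does not allow
    (empty ROI, mismatched scales, missing group, ...)."""


class ConvergenceError(CamoquantError, RuntimeError):
    """An iterative fit failed to converge."""
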