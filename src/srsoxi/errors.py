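"""Exception types raised across the package."""


class SrsoxiError(Exception):
    """Base class for all package-specific errors."""


class UnknownPresetError(SrsoxiError):
    """Requested tissue preset or wavelength is not defined."""


class ModelValidationError(SrsoxiError):
    """A tissue model or optical-property set violates an invariant."""


class ConfigValidationError(SrsoxiError):
    """A run/workbench configuration value violates a precondition."""


class AnisotropyRangeError(SrsoxiError):
    """Henyey-Greenstein anisotropy outside [0, 1)."""


class EmptyRingError(SrsoxiError):
    """A detector ring collected no weight, so mean path lengths are undefined."""

    def __init__(self, msg, ring=None):
        super().__init__(msg)
        self.ring = ring


class GeometryMismatchError(SrsoxiError):
    """Two grids/profiles that must share geometry do not."""


class InsufficientStatisticsError(SrsoxiError):
    """A detector ring's Monte Carlo error is too large for the requested
    analysis (its mean-path profile would be noise-dominated)."""

    def __init__(self, msg, ring_interval=None, rel_se=None):
        super().__init__(msg)
        self.ring_interval = ring_interval
        self.rel_se = rel_se


class MemoryGuardError(SrsoxiError):
    """A full-3D tally would exceed the configured memory budget."""


class NonMonotoneSlopeError(SrsoxiError):
    """A slope lookup table is not strictly increasing in absorption."""


class ProbeMismatchError(SrsoxiError):
    """A reading and a LUT refer to different probes or wavelengths."""


class RankDeficientError(SrsoxiError):
    """Regression design matrix does not span both predictors."""


class NonPositiveProfileError(SrsoxiError):
    """A sensitivity profile has no positive maximum to normalize against."""
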