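"""Error types shared across the pipeline stages."""


class SrsyncError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SrsyncError, ValueError):
    """A simulation or run configuration violates its invariants."""


class UnsupportedEpochError(SrsyncError, ValueError):
    """Epoch too short for the requested wavelet, or no valid samples."""


class DegenerateBaselineError(SrsyncError, ValueError):
    """Baseline power is zero or no valid baseline samples exist."""


class EmptyWindowError(SrsyncError, ValueError):
    """A time-frequency window contains no valid pixels."""


class AlignmentError(SrsyncError, ValueError):
    """Trial counts, grids or mask shapes do not match across inputs."""


class InsufficientDataError(SrsyncError, ValueError):
    """Too few subjects/values for the requested statistic."""


class ResolutionError(SrsyncError, ValueError):
    """Too few resamples to resolve the requested significance level."""


class InfeasibleError(SrsyncError, ValueError):
    """No feasible threshold exists (e.g. binomial k_min beyond n)."""


class FormatError(SrsyncError, ValueError):
    """On-disk epochs container violates the expected layout."""
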