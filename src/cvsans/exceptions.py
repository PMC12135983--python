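"""Exception hierarchy for cvsans."""


class CvsansError(Exception):
    """Base class for all cvsans errors."""


class InvalidInputError(CvsansError, ValueError):
    """Malformed user input (non-finite contrasts, out-of-range fractions, ...)."""


class InvalidSystemError(CvsansError, ValueError):
    """A linear system that cannot be posed (e.g. fewer than two components)."""


class InvalidKernelError(CvsansError, ValueError):
    """Kernel specification with non-positive amplitude or length scale."""


class InvalidRangeError(CvsansError, ValueError):
    """A Q-range restriction that leaves no data."""


class GridMismatchError(CvsansError, ValueError):
    """Intensity tables whose Q columns do not agree."""


class UnderdeterminedSystemError(CvsansError, ValueError):
    """WLS requested with fewer independent contrasts than partial functions."""


class ConditioningError(CvsansError, RuntimeError):
    """Covariance factorization failed even after jitter escalation."""


class SelectionError(CvsansError, RuntimeError):
    """Every candidate in a kernel-parameter search failed to evaluate."""
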