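"""Shared dense linear-algebra helpers (jittered Cholesky)."""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg

from .exceptions import ConditioningError

logger = logging.getLogger(__name__)

# Jitter ladder: additive diagonal of eps*scale with eps escalating x10 per retry.
_JITTER_START = 1e-12
_JITTER_MAX = 1e-6


def cholesky_with_jitter(mat: np.ndarray, scale: float | None = None,
                         context: str = "") -> tuple[np.ndarray, float]:
    """Lower-triangular Cholesky factor of a symmetric matrix, stabilized by jitter.

    Tries a plain factorization first; on failure adds ``eps * scale`` to the
    diagonal with ``eps`` escalating from 1e-12 to 1e-6 in decade steps, logging
    each escalation.  ``scale`` defaults to the mean diagonal of ``mat``.

    Returns ``(L, jitter)`` where ``jitter`` is the diagonal shift actually used.

    Raises
    ------
    ConditioningError
        If the factorization still fails at the largest jitter.
    """
    mat = np.asarray(mat, dtype=float)
    if scale is None:
        scale = float(np.mean(np.diag(mat)))
        if scale <= 0:
            scale = 1.0
    try:
        return linalg.cholesky(mat, lower=True), 0.0
    except linalg.LinAlgError:
        pass
    eps = _JITTER_START
    eye = np.eye(mat.shape[0])
    while eps <= _JITTER_MAX * (1 + 1e-12):
        jitter = eps * scale
        logger.warning("Cholesky failed%s; retrying with jitter %.3g",
                       f" ({context})" if context else "", jitter)
        try:
            return linalg.cholesky(mat + jitter * eye, lower=True), jitter
        except linalg.LinAlgError:
            eps *= 10.0
    raise ConditioningError(
        f"covariance factorization failed after jitter escalation to "
        f"{_JITTER_MAX * scale:.3g}" + (f" ({context})" if context else ""))


def chol_solve(chol_lower: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve ``A x = b`` given the lower Cholesky factor of ``A``."""
    return linalg.cho_solve((chol_lower, True), b)


def chol_logdet(chol_lower: np.ndarray) -> float:
    """log det A from the lower Cholesky factor of A."""
    return 2.0 * float(np.sum(np.log(np.diag(chol_lower))))
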