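"""Stationary covariance kernels encoding smoothness of S(Q) along Q.

The prior on each partial scattering function is a zero-mean Gaussian process
with covariance k(P, Q) depending only on r = |P - Q|:

    gaussian : k = alpha * exp(-r^2 / (2 l^2))
    matern32 : k = alpha * (1 + sqrt(3) r/l) * exp(-sqrt(3) r/l)
    matern52 : k = alpha * (1 + sqrt(5) r/l + 5 r^2/(3 l^2)) * exp(-sqrt(5) r/l)

plus an optional white (nugget) term tau^2 * [P == Q].  ``alpha`` is the prior
variance: larger alpha means a weaker smoothing effect, and alpha -> infinity
recovers weighted least squares.  ``l`` (A^-1 on the Q axis) sets how far
information travels along Q; very large l forces flat estimates.  The Matern
nu parameter controls differentiability of sample paths (once for 3/2, twice
for 5/2; the Gaussian kernel is infinitely smooth).  A small positive tau
(default 1e-5) stabilizes the Gaussian kernel's near-singular covariances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contrast import QGrid
from .exceptions import InvalidKernelError

__all__ = ["KernelSpec", "kernel_value", "kernel_matrix", "KERNEL_FAMILIES"]

KERNEL_FAMILIES = ("gaussian", "matern32", "matern52")

_SQRT3 = np.sqrt(3.0)
_SQRT5 = np.sqrt(5.0)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus the (alpha, l, tau) parameters of the prior.

    Parameters
    ----------
    family : {"gaussian", "matern32", "matern52"}
    alpha : float
        Prior-variance scale, > 0.
    length_scale : float
        Correlation length on the Q axis, A^-1, > 0.
    tau : float
        White-kernel scale; tau^2 is added on the diagonal.  Default 1e-5.
    log_q : bool
        If True, distances are measured on log(Q) instead of Q.  Off by
        default; ``length_scale`` is then in decades times ln 10.
    """

    family: str
    alpha: float
    length_scale: float
    tau: float = 1e-5
    log_q: bool = False

    def __post_init__(self):
        if self.family not in KERNEL_FAMILIES:
            raise InvalidKernelError(
                f"unknown kernel family {self.family!r}; choose from {KERNEL_FAMILIES}")
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise InvalidKernelError(f"alpha must be positive, got {self.alpha}")
        if not (np.isfinite(self.length_scale) and self.length_scale > 0):
            raise InvalidKernelError(
                f"length_scale must be positive, got {self.length_scale}")
        if not (np.isfinite(self.tau) and self.tau >= 0):
            raise InvalidKernelError(f"tau must be non-negative, got {self.tau}")

    def describe(self) -> str:
        return (f"{self.family}(alpha={self.alpha:g}, l={self.length_scale:g}, "
                f"tau={self.tau:g}{', log-Q' if self.log_q else ''})")


def _stationary(spec: KernelSpec, r: np.ndarray) -> np.ndarray:
    u = r / spec.length_scale
    if spec.family == "gaussian":
        return spec.alpha * np.exp(-0.5 * u * u)
    if spec.family == "matern32":
        s = _SQRT3 * u
        return spec.alpha * (1.0 + s) * np.exp(-s)
    # matern52
    s = _SQRT5 * u
    return spec.alpha * (1.0 + s + s * s / 3.0) * np.exp(-s)


def kernel_value(spec: KernelSpec, p, q) -> np.ndarray | float:
    """Covariance k(P, Q); symmetric and stationary in |P - Q|.

    The white term tau^2 is added where P == Q exactly.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    same = p == q
    if spec.log_q:
        p, q = np.log(p), np.log(q)
    r = np.abs(p - q)
    val = _stationary(spec, r) + spec.tau ** 2 * same
    return float(val) if val.ndim == 0 else val


def kernel_matrix(spec: KernelSpec, qgrid: QGrid) -> np.ndarray:
    """M x M prior covariance D over the grid: D[m, m'] = k(Q_m, Q_m').

    Symmetric with diagonal alpha + tau^2; positive semidefinite up to the
    numerical tolerance handled downstream by jittered factorization.
    """
    q = qgrid.values
    x = np.log(q) if spec.log_q else q
    r = np.abs(x[:, None] - x[None, :])
    d = _stationary(spec, r)
    d[np.diag_indices_from(d)] += spec.tau ** 2
    return d
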