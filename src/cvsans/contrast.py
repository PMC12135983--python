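"""Samples, contrasts and the flattened linear system of CV-SANS decomposition.

A contrast-variation experiment measures the same p-component system N times
with different solvent compositions.  Each measured intensity is a quadratic
mixture of L = p(p-1)/2 latent partial scattering functions S_ij(Q):

    I_n(Q) = sum_{i<=j} A[n, (i,j)] S_ij(Q),
    A[n, (i,i)] = drho_{n,i}^2,   A[n, (i,j)] = 2 drho_{n,i} drho_{n,j}  (i < j),

where drho_{n,i} is the scattering-length-density contrast of solute i against
the solvent in sample n.  This module holds the data containers (Q grid,
contrast set, intensity matrix) and builds the design matrix A and the flat
(vectorized) linear system used by the estimators.

Units: contrasts are carried in 1e-6 A^-2, so A entries are O(1-100) and the
linear algebra is well scaled; the partial functions inherit the reciprocal
units.  The factor 2 on cross terms lives in A, never in S: each unordered
pair is reported once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError, InvalidSystemError

__all__ = [
    "QGrid", "ContrastSet", "IntensityData", "FlatSystem",
    "pair_index_order", "build_design_matrix", "flatten_system",
]


@dataclass(frozen=True)
class QGrid:
    """Strictly increasing grid of scattering-vector magnitudes, in A^-1."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise InvalidInputError("Q grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("Q grid contains non-finite values")
        if np.any(v <= 0):
            raise InvalidInputError("Q values must be strictly positive")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            raise InvalidInputError("Q grid must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size

    @property
    def span(self) -> float:
        """Q_max - Q_min of the grid."""
        return float(self.values[-1] - self.values[0])


@dataclass(frozen=True)
class ContrastSet:
    """Per-sample solute contrasts defining the mixing matrix of the experiment.

    Parameters
    ----------
    sample_names : list of str, length N
    deltas : (N, p-1) array
        Contrast drho_{n,i} = rho_i - rho_solvent of each solute against the
        solvent of sample n, in 1e-6 A^-2.
    component_names : list of str, length p-1
    """

    sample_names: tuple[str, ...]
    deltas: np.ndarray
    component_names: tuple[str, ...]

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.deltas, dtype=float))
        object.__setattr__(self, "deltas", d)
        object.__setattr__(self, "sample_names", tuple(self.sample_names))
        object.__setattr__(self, "component_names", tuple(self.component_names))
        n, q = d.shape
        if n < 1 or q < 1:
            raise InvalidSystemError("need at least one sample and one solute")
        if len(self.sample_names) != n:
            raise InvalidInputError("sample_names length does not match deltas rows")
        if len(self.component_names) != q:
            raise InvalidInputError("component_names length does not match deltas columns")
        if not np.all(np.isfinite(d)):
            raise InvalidInputError("non-finite contrast value")
        uniq = {tuple(row) for row in d}
        if len(uniq) < n:
            warnings.warn("duplicate contrast rows: samples carry redundant "
                          "information for the decomposition", stacklevel=2)

    @property
    def n_samples(self) -> int:
        return self.deltas.shape[0]

    @property
    def n_components(self) -> int:
        """Number of solutes, p - 1."""
        return self.deltas.shape[1]

    @property
    def p(self) -> int:
        """Total component count including the solvent."""
        return self.deltas.shape[1] + 1

    def pair_labels(self) -> list[str]:
        """Human-readable labels for the partial functions, in canonical order."""
        names = self.component_names
        return [f"{names[i - 1]}-{names[j - 1]}"
                for i, j in pair_index_order(self.p)]


@dataclass(frozen=True)
class IntensityData:
    """N scattering curves with per-point 1-sigma errors on a shared Q grid."""

    qgrid: QGrid
    intensities: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self):
        i = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        s = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
        object.__setattr__(self, "intensities", i)
        object.__setattr__(self, "sigmas", s)
        m = len(self.qgrid)
        if i.shape[1] != m:
            raise InvalidInputError(
                f"intensities have {i.shape[1]} columns but Q grid has {m} points")
        if s.shape != i.shape:
            raise InvalidInputError("sigmas shape does not match intensities")
        if not np.all(np.isfinite(i)):
            raise InvalidInputError("non-finite intensity")
        if not (np.all(np.isfinite(s)) and np.all(s > 0)):
            raise InvalidInputError("all sigmas must be finite and strictly positive")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_q(self) -> int:
        return self.intensities.shape[1]

    def restrict(self, mask: np.ndarray) -> "IntensityData":
        """Restrict to the Q points selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return IntensityData(QGrid(self.qgrid.values[mask]),
                             self.intensities[:, mask], self.sigmas[:, mask])


@dataclass(frozen=True)
class FlatSystem:
    """Vectorized observation model I~ = B S~ + eps.

    Latent ordering is pair-major, Q-minor: (S_1(Q_1)..S_1(Q_M), S_2(Q_1)..);
    observation ordering is sample-major, Q-minor.  Under these orderings
    B = A (x) E_M (Kronecker product with the M-point identity).
    """

    design: np.ndarray          # (N*M, L*M)
    observations: np.ndarray    # (N*M,)
    noise_cov_diag: np.ndarray  # (N*M,) variances sigma^2
    n_samples: int
    n_q: int
    n_pairs: int

    def row_index(self, n: int, m: int) -> int:
        """Flat row of observation (sample n, Q point m); 0-based."""
        return n * self.n_q + m

    def col_index(self, ell: int, m: int) -> int:
        """Flat column of latent (pair ell, Q point m); 0-based."""
        return ell * self.n_q + m


def pair_index_order(p: int) -> list[tuple[int, int]]:
    """Canonical ordering of the L = p(p-1)/2 component pairs.

    Pairs of solute indices (i, j), 1-based, i <= j, in lexicographic order:
    (1,1), (1,2), ..., (1,p-1), (2,2), ..., (p-1,p-1).  Self terms and cross
    terms are interleaved by this rule; all outputs of the package use it.
    """
    if p < 2:
        raise InvalidSystemError(f"need at least two components, got p={p}")
    return [(i, j) for i in range(1, p) for j in range(i, p)]


def build_design_matrix(contrasts: ContrastSet) -> np.ndarray:
    """Design matrix A mapping partial functions to intensities.

    ``A[n, (i,j)] = drho_{n,i}^2`` for self terms and ``2 drho_{n,i} drho_{n,j}``
    for cross terms, columns in :func:`pair_index_order`.  Units (1e-6 A^-2)^2.
    """
    d = contrasts.deltas
    pairs = pair_index_order(contrasts.p)
    a = np.empty((contrasts.n_samples, len(pairs)))
    for col, (i, j) in enumerate(pairs):
        if i == j:
            a[:, col] = d[:, i - 1] ** 2
        else:
            a[:, col] = 2.0 * d[:, i - 1] * d[:, j - 1]
    return a


def flatten_system(a: np.ndarray, data: IntensityData) -> FlatSystem:
    """Vectorize the per-Q mixing into one block system B = A (x) E_M."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    n, ell = a.shape
    m = data.n_q
    if data.n_samples != n:
        raise InvalidInputError(
            f"design matrix has {n} rows but data has {data.n_samples} samples")
    b = np.kron(a, np.eye(m))
    return FlatSystem(design=b,
                      observations=data.intensities.ravel(),
                      noise_cov_diag=(data.sigmas ** 2).ravel(),
                      n_samples=n, n_q=m, n_pairs=ell)
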