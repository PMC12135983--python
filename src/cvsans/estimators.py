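"""Posterior and least-squares estimators of partial scattering functions.

Two estimators share one interface:

``GPRPartials``
    Exact linear-Gaussian posterior under a Gaussian-process prior.  With the
    latent vector S~ (pair-major, Q-minor), design B = A (x) E_M, noise
    covariance Sigma~ = diag(sigma^2) and prior S~ ~ N(0, K~) with
    K~ = E_L (x) D, the posterior is Gaussian with

        mean = K~ B' (B K~ B' + Sigma~)^-1 I~
        cov  = K~ - K~ B' (B K~ B' + Sigma~)^-1 B K~,

    equal to the precision form V = B' Sigma~^-1 B + K~^-1, mean = V^-1 B'
    Sigma~^-1 I~.  Numerically both are evaluated through the whitened
    weight-space factorization: D = R R' (Cholesky with escalating diagonal
    jitter on failure), Phi = Sigma~^(-1/2) (A (x) R) and the thin SVD
    Phi = U diag(s) V', giving

        mean = (E_L (x) R) V diag(s / (1 + s^2)) U' Sigma~^(-1/2) I~
        cov  = Z diag(1 / (1 + s^2)) Z',   Z = (E_L (x) R) V,

    which is algebraically identical but keeps full accuracy across the whole
    amplitude range (the shrinkage factors s/(1+s^2) and 1/(1+s^2) involve no
    cancellation), so the diffuse-prior limit reproduces weighted least
    squares to solver precision.  No explicit inverse of K~ is ever formed;
    independence of the L functions in the prior makes K~ block diagonal.

``WLSPartials``
    Weighted least squares independently at each Q point: the unbiased
    baseline.  Estimate (A' W A)^-1 A' W I with W = diag(1/sigma^2) per point,
    covariance (A' W A)^-1 (no degrees-of-freedom correction).

Both follow the scikit-learn estimator protocol: construct with
hyperparameters, ``fit(data, contrasts)``, then read fitted attributes
(``means_``, ``stderr_``, ``covariance_``, ``log_marginal_likelihood_``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from ._linalg import cholesky_with_jitter
from .contrast import ContrastSet, IntensityData, QGrid, build_design_matrix
from .exceptions import InvalidInputError, UnderdeterminedSystemError
from .kernels import KernelSpec, kernel_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PartialEstimate", "GPRPartials", "WLSPartials",
    "prior_covariance", "fit_gpr", "fit_wls", "error_bars",
]


@dataclass
class PartialEstimate:
    """Estimated partial scattering functions with pointwise error bars.

    ``means`` and ``stderr`` are (L, M) in the canonical pair order;
    ``covariance`` (optional) is the full (L*M, L*M) posterior covariance in
    pair-major, Q-minor layout, so its diagonal equals ``stderr.ravel()**2``.
    """

    qgrid: QGrid
    means: np.ndarray
    stderr: np.ndarray
    pair_labels: list[str]
    method: str                      # "gpr" or "wls"
    kernel: KernelSpec | None = None
    log_marginal_likelihood: float | None = None
    covariance: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return self.means.shape[0]

    @property
    def n_q(self) -> int:
        return self.means.shape[1]


def prior_covariance(spec: KernelSpec, qgrid: QGrid, n_pairs: int) -> np.ndarray:
    """(L*M, L*M) prior covariance E_L (x) D: block diagonal, one D per pair.

    Cross-pair blocks are exactly zero — the prior assumes the L partial
    functions are statistically independent.
    """
    if n_pairs < 1:
        raise InvalidInputError("need at least one partial function")
    d = kernel_matrix(spec, qgrid)
    return np.kron(np.eye(n_pairs), d)


def _check_inputs(data: IntensityData, contrasts: ContrastSet) -> np.ndarray:
    if contrasts.n_samples != data.n_samples:
        raise InvalidInputError(
            f"contrast set has {contrasts.n_samples} samples but intensity "
            f"data has {data.n_samples}")
    return build_design_matrix(contrasts)


def _whitened_svd(a: np.ndarray, data: IntensityData, spec: KernelSpec):
    """Whitened weight-space factorization of the linear-Gaussian model.

    Factors D = R R' (jittered Cholesky, jitter scaled by alpha + tau^2) and
    takes the thin SVD of Phi = Sigma~^(-1/2) (A (x) R).  Returns
    (r_chol, u, s, vt, y_white, jitter) with y_white = Sigma~^(-1/2) I~.
    """
    d = kernel_matrix(spec, data.qgrid)
    r_chol, jitter = cholesky_with_jitter(
        d, scale=spec.alpha + spec.tau ** 2, context=spec.describe())
    sig = data.sigmas.ravel()
    phi = np.kron(a, r_chol) / sig[:, None]
    u, s, vt = linalg.svd(phi, full_matrices=False)
    y_white = data.intensities.ravel() / sig
    return r_chol, u, s, vt, y_white, jitter


def _diagnose(means: np.ndarray, stderr: np.ndarray, contrasts: ContrastSet) -> dict:
    """Negativity and Cauchy-Schwarz diagnostics (reported, never enforced)."""
    from .contrast import pair_index_order
    diag = {}
    neg = (means < 0) & (means + 2.0 * stderr < 0)
    diag["negative_beyond_2se"] = [
        (contrasts.pair_labels()[ell], int(m))
        for ell, m in zip(*np.nonzero(neg))
    ]
    pairs = pair_index_order(contrasts.p)
    col = {pair: k for k, pair in enumerate(pairs)}
    violations = []
    for (i, j), k in col.items():
        if i == j:
            continue
        bound = np.sqrt(np.clip(means[col[(i, i)]] * means[col[(j, j)]], 0, None))
        bad = np.abs(means[k]) > bound
        if np.any(bad):
            violations.append((contrasts.pair_labels()[k], int(np.sum(bad))))
    diag["cauchy_schwarz_violations"] = violations
    if violations:
        logger.warning("Cauchy-Schwarz |S_ij| <= sqrt(S_ii S_jj) violated at "
                       "some Q points (informational): %s", violations)
    return diag


class GPRPartials(BaseEstimator):
    """Gaussian-process posterior estimator of partial scattering functions.

    Parameters
    ----------
    kernel : {"gaussian", "matern32", "matern52"}, default "matern52"
    alpha : float, default 1.0
        Prior variance scale; larger alpha weakens the smoothing.
    length_scale : float, default 0.1
        Correlation length on the Q axis (A^-1).
    tau : float, default 1e-5
        White-kernel scale added to the main kernel.
    log_q : bool, default False
        Measure kernel distances on log Q.
    store_covariance : bool, default False
        Keep the full (L*M, L*M) posterior covariance (O((LM)^2) memory).

    Attributes
    ----------
    means_ : (L, M) ndarray — posterior means of the partial functions.
    stderr_ : (L, M) ndarray — posterior standard deviations.
    covariance_ : ndarray or None — full posterior covariance if requested.
    log_marginal_likelihood_ : float — evidence of the data under the prior.
    estimate_ : PartialEstimate — all of the above bundled with metadata.
    """

    def __init__(self, kernel: str = "matern52", alpha: float = 1.0,
                 length_scale: float = 0.1, tau: float = 1e-5,
                 log_q: bool = False, store_covariance: bool = False):
        self.kernel = kernel
        self.alpha = alpha
        self.length_scale = length_scale
        self.tau = tau
        self.log_q = log_q
        self.store_covariance = store_covariance

    def _spec(self) -> KernelSpec:
        return KernelSpec(self.kernel, self.alpha, self.length_scale,
                          self.tau, self.log_q)

    def fit(self, data: IntensityData, contrasts: ContrastSet) -> "GPRPartials":
        spec = self._spec()
        a = _check_inputs(data, contrasts)
        m = data.n_q
        n_pairs = a.shape[1]
        r_chol, u, s, vt, y_white, jitter = _whitened_svd(a, data, spec)

        coef = u.T @ y_white                       # projections onto data modes
        shrink = s / (1.0 + s * s)                 # no cancellation at any scale
        r_kron = np.kron(np.eye(n_pairs), r_chol)
        mu = r_kron @ (vt.T @ (shrink * coef))
        z = r_kron @ vt.T                          # (LM, K) posterior basis
        var = np.einsum("ik,k,ik->i", z, 1.0 / (1.0 + s * s), z)
        # modes beyond rank(Phi) keep their prior variance
        resid = (spec.alpha + spec.tau ** 2 + jitter) - np.einsum("ik,ik->i", z, z)
        var = var + np.clip(resid, 0.0, None)

        lml = (-0.5 * (float(y_white @ y_white)
                       - float(np.sum((s * s / (1.0 + s * s)) * coef ** 2)))
               - float(np.sum(np.log(data.sigmas)))
               - 0.5 * float(np.sum(np.log1p(s * s)))
               - 0.5 * y_white.size * np.log(2.0 * np.pi))

        self.means_ = mu.reshape(n_pairs, m)
        self.stderr_ = np.sqrt(np.clip(var, 0.0, None)).reshape(n_pairs, m)
        if self.store_covariance:
            # cov = Z diag(1/(1+s^2)) Z' plus the prior in the unresolved modes
            cov = (z / (1.0 + s * s)) @ z.T
            full_prior = prior_covariance(spec, data.qgrid, n_pairs)
            cov += full_prior - z @ z.T
            cov = 0.5 * (cov + cov.T)
            self.covariance_ = cov
        else:
            self.covariance_ = None
        self.log_marginal_likelihood_ = lml
        self.jitter_ = jitter
        diagnostics = _diagnose(self.means_, self.stderr_, contrasts)
        diagnostics["jitter"] = jitter
        self.estimate_ = PartialEstimate(
            qgrid=data.qgrid, means=self.means_, stderr=self.stderr_,
            pair_labels=contrasts.pair_labels(), method="gpr", kernel=spec,
            log_marginal_likelihood=lml, covariance=self.covariance_,
            diagnostics=diagnostics)
        return self

    def score(self, data: IntensityData, contrasts: ContrastSet) -> float:
        """Log marginal likelihood of ``data`` under this kernel (no fit stored)."""
        return log_marginal_likelihood(data, contrasts, self._spec())


def log_marginal_likelihood(data: IntensityData, contrasts: ContrastSet,
                            spec: KernelSpec) -> float:
    """Evidence log N(I~; 0, B K~ B' + Sigma~).

    Computed from the whitened-design SVD: the log-determinant is
    sum log sigma^2 + sum log(1 + s_k^2) — never a raw determinant.
    """
    a = _check_inputs(data, contrasts)
    _, u, s, _, y_white, _ = _whitened_svd(a, data, spec)
    coef = u.T @ y_white
    quad = float(y_white @ y_white) - float(
        np.sum((s * s / (1.0 + s * s)) * coef ** 2))
    logdet = 2.0 * float(np.sum(np.log(data.sigmas))) + float(
        np.sum(np.log1p(s * s)))
    return -0.5 * (quad + logdet + y_white.size * np.log(2.0 * np.pi))


class WLSPartials(BaseEstimator):
    """Per-Q weighted least-squares baseline with propagated error bars.

    Requires N >= L samples and a full-column-rank design; rank deficiency is
    an error (no silent pseudo-inverse), so comparisons against the smoothing
    estimator stay honest.  Attributes after ``fit`` mirror ``GPRPartials``
    (``covariance_`` is block diagonal across Q points when requested).
    """

    def __init__(self, store_covariance: bool = False):
        self.store_covariance = store_covariance

    def fit(self, data: IntensityData, contrasts: ContrastSet) -> "WLSPartials":
        a = _check_inputs(data, contrasts)
        n, n_pairs = a.shape
        m = data.n_q
        if n < n_pairs:
            raise UnderdeterminedSystemError(
                f"{n} samples cannot determine {n_pairs} partial functions; "
                "this holds at every Q point")
        if np.linalg.matrix_rank(a) < n_pairs:
            raise UnderdeterminedSystemError(
                "design matrix is rank deficient (contrasts are collinear); "
                "this holds at every Q point")
        means = np.empty((n_pairs, m))
        stderr = np.empty((n_pairs, m))
        covs = np.empty((m, n_pairs, n_pairs)) if self.store_covariance else None
        for j in range(m):
            w = 1.0 / data.sigmas[:, j] ** 2
            awa = (a * w[:, None]).T @ a
            try:
                cov = linalg.inv(awa)
            except linalg.LinAlgError as exc:  # pragma: no cover - rank checked above
                raise UnderdeterminedSystemError(
                    f"normal matrix singular at Q index {j}") from exc
            means[:, j] = cov @ (a.T @ (w * data.intensities[:, j]))
            stderr[:, j] = np.sqrt(np.diag(cov))
            if covs is not None:
                covs[j] = cov
        self.means_ = means
        self.stderr_ = stderr
        if covs is not None:
            # assemble pair-major, Q-minor block-diagonal covariance
            lm = n_pairs * m
            full = np.zeros((lm, lm))
            for j in range(m):
                idx = j + m * np.arange(n_pairs)
                full[np.ix_(idx, idx)] = covs[j]
            self.covariance_ = full
        else:
            self.covariance_ = None
        self.log_marginal_likelihood_ = None
        diagnostics = _diagnose(means, stderr, contrasts)
        self.estimate_ = PartialEstimate(
            qgrid=data.qgrid, means=means, stderr=stderr,
            pair_labels=contrasts.pair_labels(), method="wls", kernel=None,
            log_marginal_likelihood=None, covariance=self.covariance_,
            diagnostics=diagnostics)
        return self


def fit_gpr(data: IntensityData, contrasts: ContrastSet, spec: KernelSpec,
            want_cov: bool = False) -> PartialEstimate:
    """Posterior estimate of the partial functions under the given kernel."""
    est = GPRPartials(kernel=spec.family, alpha=spec.alpha,
                      length_scale=spec.length_scale, tau=spec.tau,
                      log_q=spec.log_q, store_covariance=want_cov)
    return est.fit(data, contrasts).estimate_


def fit_wls(data: IntensityData, contrasts: ContrastSet,
            want_cov: bool = False) -> PartialEstimate:
    """Weighted least-squares estimate, independently at each Q point."""
    est = WLSPartials(store_covariance=want_cov)
    return est.fit(data, contrasts).estimate_


def error_bars(est: PartialEstimate) -> np.ndarray:
    """(L, M) posterior standard deviations of an estimate."""
    if est.stderr is not None:
        return est.stderr
    if est.covariance is None:
        raise InvalidInputError("estimate carries neither stderr nor covariance")
    var = np.clip(np.diag(est.covariance), 0.0, None)
    return np.sqrt(var).reshape(est.n_pairs, est.n_q)
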