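"""Kernel-parameter selection: subjective choice, MAP with a hyper-prior, or
empirical Bayes by grid search over the log marginal likelihood.

Selecting (alpha, l) after looking at the estimated curves would let the
analyst steer the result; the selection methods here fix the rule in advance.
The empirical-Bayes route maximizes the evidence log p(I~ | theta) over a
parameter grid; the MAP route adds the log density of a hyper-prior p(theta)
and reduces to empirical Bayes as the hyper-prior widens.  Kernel *family*
selection is reported side by side but never automated: evidence values of
different families are typically too close to discriminate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .contrast import ContrastSet, IntensityData
from .estimators import GPRPartials, log_marginal_likelihood
from .exceptions import InvalidInputError, SelectionError
from .kernels import KERNEL_FAMILIES, KernelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ParamPrior", "HyperPrior", "SelectionResult",
    "map_objective", "grid_search", "KernelGridSearch",
    "log_marginal_likelihood",
]

#: objective values within this of the maximum are treated as tied
TIE_TOL = 1e-6


@dataclass(frozen=True)
class ParamPrior:
    """Hyper-prior on a single positive kernel parameter.

    families:
      * ``gaussian``  — penalty -(x - loc)^2 / (2 scale^2); the normalizer is
        dropped because it does not depend on the parameter.
      * ``lognormal`` — full log density with median ``loc`` and log-space
        standard deviation ``scale`` (respects positivity).
      * ``uniform``   — 0 inside [loc, scale] (bounds), -inf outside.
    """

    family: str = "lognormal"
    loc: float = 1.0
    scale: float = 1.0

    def __post_init__(self):
        if self.family not in ("gaussian", "lognormal", "uniform"):
            raise InvalidInputError(f"unknown hyper-prior family {self.family!r}")
        if self.family == "uniform":
            if not self.loc < self.scale:
                raise InvalidInputError("uniform hyper-prior bounds must be ordered")
        elif self.scale <= 0:
            raise InvalidInputError("hyper-prior scale must be positive")

    def log_density(self, x: float) -> float:
        if self.family == "gaussian":
            return -0.5 * ((x - self.loc) / self.scale) ** 2
        if self.family == "lognormal":
            return float(stats.lognorm.logpdf(x, s=self.scale, scale=self.loc))
        return 0.0 if self.loc <= x <= self.scale else -np.inf


@dataclass(frozen=True)
class HyperPrior:
    """Independent hyper-priors on alpha and on the length scale."""

    alpha: ParamPrior = field(default_factory=ParamPrior)
    length_scale: ParamPrior = field(default_factory=ParamPrior)

    def log_density(self, spec: KernelSpec) -> float:
        return (self.alpha.log_density(spec.alpha)
                + self.length_scale.log_density(spec.length_scale))


@dataclass
class SelectionResult:
    """Outcome of a kernel-parameter search.

    ``table`` is the exhaustive list of (spec, objective value); ``best_spec``
    attains the maximum under the tie rule recorded in ``ties_broken_by``.
    """

    best_spec: KernelSpec
    objective_name: str
    table: list[tuple[KernelSpec, float]]
    ties_broken_by: str

    def by_family(self) -> dict[str, tuple[KernelSpec, float]]:
        """Best (spec, objective) per kernel family, for side-by-side reporting."""
        out: dict[str, tuple[KernelSpec, float]] = {}
        for spec, val in self.table:
            if np.isfinite(val) and (spec.family not in out or val > out[spec.family][1]):
                out[spec.family] = (spec, val)
        return out


def map_objective(data: IntensityData, contrasts: ContrastSet,
                  spec: KernelSpec, hyper: HyperPrior) -> float:
    """Log evidence plus log hyper-prior density at (alpha, l).

    Constants independent of the kernel parameters are dropped.  Parameters
    outside a uniform hyper-prior's support give -inf (excluded, not an
    error).  As the hyper-prior scales grow this tends to the plain log
    marginal likelihood.
    """
    penalty = hyper.log_density(spec)
    if penalty == -np.inf:
        return -np.inf
    return log_marginal_likelihood(data, contrasts, spec) + penalty


def _sort_key(spec: KernelSpec):
    fam_order = {f: i for i, f in enumerate(KERNEL_FAMILIES)}
    return (fam_order[spec.family], spec.alpha, spec.length_scale, spec.tau)


def _select(table: list[tuple[KernelSpec, float]]) -> KernelSpec:
    finite = [(s, v) for s, v in table if np.isfinite(v)]
    if not finite:
        raise SelectionError("no kernel candidate produced a finite objective")
    vmax = max(v for _, v in finite)
    tied = [s for s, v in finite if v >= vmax - TIE_TOL]
    # prefer smaller l, then smaller alpha, then family order
    tied.sort(key=lambda s: (s.length_scale, s.alpha, _sort_key(s)))
    return tied[0]


def _geometric_midpoints(grid: np.ndarray, winner: float) -> list[float]:
    """Midpoints (geometric) between the winner and its grid neighbours."""
    grid = np.sort(np.asarray(grid, dtype=float))
    idx = int(np.argmin(np.abs(np.log(grid) - np.log(winner))))
    out = []
    if idx > 0:
        out.append(float(np.sqrt(grid[idx - 1] * grid[idx])))
    if idx < grid.size - 1:
        out.append(float(np.sqrt(grid[idx] * grid[idx + 1])))
    return out


def grid_search(data: IntensityData, contrasts: ContrastSet,
                families=("matern52",),
                alpha_grid=None, l_grid=None, tau: float = 1e-5,
                objective: str = "lml", hyper: HyperPrior | None = None,
                refine: bool = False, log_q: bool = False) -> SelectionResult:
    """Exhaustive search over (family, alpha, l) maximizing the objective.

    Default grids are 6 log-spaced decades, alpha and l in [1e-3, 1e2]; tau is
    held fixed.  ``objective`` is ``"lml"`` (empirical Bayes) or ``"map"``
    (requires ``hyper``).  With ``refine=True`` one extra pass doubles the
    grid density around the winner (geometric midpoints to its neighbours)
    and re-selects.  The returned table is exhaustive and deterministically
    sorted; ties within 1e-6 prefer smaller l, then smaller alpha.
    """
    if alpha_grid is None:
        alpha_grid = np.logspace(-3, 2, 6)
    if l_grid is None:
        l_grid = np.logspace(-3, 2, 6)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    l_grid = np.asarray(l_grid, dtype=float)
    if alpha_grid.size == 0 or l_grid.size == 0 or not families:
        raise InvalidInputError("parameter grids and family list must be non-empty")
    if objective == "map":
        if hyper is None:
            hyper = HyperPrior()
    elif objective != "lml":
        raise InvalidInputError(f"unknown objective {objective!r}")

    def evaluate(spec: KernelSpec) -> float:
        try:
            if objective == "lml":
                return log_marginal_likelihood(data, contrasts, spec)
            return map_objective(data, contrasts, spec, hyper)
        except Exception as exc:  # conditioning failures become -inf entries
            logger.warning("objective failed for %s: %s", spec.describe(), exc)
            return -np.inf

    table: list[tuple[KernelSpec, float]] = []
    for fam in families:
        for a in alpha_grid:
            for l in l_grid:
                spec = KernelSpec(fam, float(a), float(l), tau, log_q)
                table.append((spec, evaluate(spec)))
    if all(not np.isfinite(v) for _, v in table):
        raise SelectionError(
            "all kernel-parameter evaluations failed; "
            f"families={families}, {len(table)} candidates")
    best = _select(table)

    if refine:
        extra_a = [best.alpha] + _geometric_midpoints(alpha_grid, best.alpha)
        extra_l = [best.length_scale] + _geometric_midpoints(l_grid, best.length_scale)
        seen = {(s.family, s.alpha, s.length_scale) for s, _ in table}
        for a in extra_a:
            for l in extra_l:
                key = (best.family, float(a), float(l))
                if key in seen:
                    continue
                spec = KernelSpec(best.family, float(a), float(l), tau, log_q)
                table.append((spec, evaluate(spec)))
        best = _select(table)

    table.sort(key=lambda item: _sort_key(item[0]))
    return SelectionResult(
        best_spec=best, objective_name=objective, table=table,
        ties_broken_by="smaller length_scale, then smaller alpha")


class KernelGridSearch(BaseEstimator):
    """Grid-search kernel selection wrapped as an estimator.

    ``fit`` runs :func:`grid_search`, then refits :class:`GPRPartials` with
    the winning kernel.  Fitted attributes: ``best_spec_``, ``result_``,
    ``best_estimator_`` plus the usual ``means_`` / ``stderr_`` forwarded
    from the winning fit.
    """

    def __init__(self, families=("matern52",), alpha_grid=None, l_grid=None,
                 tau: float = 1e-5, objective: str = "lml",
                 hyper: HyperPrior | None = None, refine: bool = False,
                 log_q: bool = False, store_covariance: bool = False):
        self.families = families
        self.alpha_grid = alpha_grid
        self.l_grid = l_grid
        self.tau = tau
        self.objective = objective
        self.hyper = hyper
        self.refine = refine
        self.log_q = log_q
        self.store_covariance = store_covariance

    def fit(self, data: IntensityData, contrasts: ContrastSet) -> "KernelGridSearch":
        self.result_ = grid_search(
            data, contrasts, families=self.families, alpha_grid=self.alpha_grid,
            l_grid=self.l_grid, tau=self.tau, objective=self.objective,
            hyper=self.hyper, refine=self.refine, log_q=self.log_q)
        spec = self.result_.best_spec
        self.best_spec_ = spec
        self.best_estimator_ = GPRPartials(
            kernel=spec.family, alpha=spec.alpha, length_scale=spec.length_scale,
            tau=spec.tau, log_q=spec.log_q,
            store_covariance=self.store_covariance).fit(data, contrasts)
        self.means_ = self.best_estimator_.means_
        self.stderr_ = self.best_estimator_.stderr_
        self.log_marginal_likelihood_ = self.best_estimator_.log_marginal_likelihood_
        self.estimate_ = self.best_estimator_.estimate_
        return self
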