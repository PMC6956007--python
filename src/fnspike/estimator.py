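"""Bounded maximum-likelihood estimation of the five FN parameters.

The estimate is

    theta_hat = argmax_theta  l(S_1, ..., S_M | theta)

over a box [lb, ub] with lb = 0 on every coordinate (all FN parameters are
positive).  The maximization runs L-BFGS-B on the negative joint
log-likelihood in internally rescaled coordinates (theta / scale, with
scale set from the box widths) so that all five search directions are
O(1); gradients are exact forward-sensitivity derivatives of the
discretized objective by default, with a finite-difference fallback.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import EstimationError, InvalidInputError
from .likelihood import (
    Dataset,
    joint_log_likelihood,
    joint_log_likelihood_with_gradient,
)
from .model import NeuronParams

__all__ = ["EstimationResult", "DEFAULT_BOUNDS", "estimate"]

#: Lower bounds are the zero floor on all five parameters; the upper
#: bounds [1, 1, 1, 1, 200] enclose the nominal values with wide margin.
DEFAULT_BOUNDS = ((0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 200.0))

#: Objective value returned to the optimizer at infeasible points.
_INFEASIBLE = 1.0e12

#: Floor applied to F inside the objective only (see note in `estimate`).
_F_FLOOR = 1.0e-12


@dataclass
class EstimationResult:
    """Outcome of one bounded ML run."""

    params: NeuronParams
    log_likelihood: float
    converged: bool
    n_iter: int
    n_fev: int
    init: NeuronParams
    bounds: tuple
    wall_seconds: float
    message: str = ""
    n_starts: int = 1
    eval_points: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.params.to_dict(),
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_fev": self.n_fev,
            "init": self.init.to_dict(),
            "bounds": [list(b) for b in self.bounds],
            "wall_seconds": self.wall_seconds,
            "message": self.message,
            "n_starts": self.n_starts,
        }


def _draw_init(bounds, rng: np.random.Generator) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if not np.all(np.isfinite(hi)):
        raise InvalidInputError("random initialization requires finite upper bounds")
    return rng.uniform(lo, hi)


def estimate(
    dataset: Dataset,
    bounds=DEFAULT_BOUNDS,
    init: NeuronParams | None = None,
    seed=None,
    gradient: str = "analytic",
    maxiter: int = 500,
    ftol: float = 1e-12,
    gtol: float = 1e-3,
    multistart: int = 3,
    track_evals: bool = False,
) -> EstimationResult:
    """Maximize the joint log-likelihood over a box.

    Parameters
    ----------
    dataset : Dataset
    bounds : five (lower, upper) pairs
        Lower edges must be >= 0.
    init : NeuronParams, optional
        Starting point; must lie within bounds.  If omitted, one uniform
        draw within the bounds is taken per start from a generator seeded
        by ``seed``.
    seed : int | numpy Generator, optional
        Source of randomness for random initialization.
    gradient : "analytic" | "numeric"
        Exact forward-sensitivity gradient (default) or L-BFGS-B's own
        finite differences.
    multistart : int
        Number of random starts; the best final objective wins.  With an
        explicit ``init``, the first start uses it and any further starts
        are random.  The default of 3 guards against the occasional local
        optimum on the weakly identified (a, b) ridge of the likelihood.
    track_evals : bool
        Record every parameter point at which the objective was evaluated
        (for bound-respect diagnostics).

    Returns
    -------
    EstimationResult, with ``log_likelihood`` finite on success.

    Raises
    ------
    EstimationError if no start produced a finite objective.
    InvalidInputError if ``init`` lies outside the bounds.
    """
    if len(dataset) < 1:
        raise InvalidInputError("dataset must be non-empty")
    bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    if len(bounds) != 5 or any(lo < 0 or hi < lo for lo, hi in bounds):
        raise InvalidInputError("bounds must be five [lo, hi] pairs with 0 <= lo <= hi")
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if init is not None:
        theta0 = init.as_array()
        if np.any(theta0 < lo) or np.any(theta0 > hi):
            raise InvalidInputError("initial guess lies outside the bounds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # rescale so every coordinate spans O(1): theta = z * scale
    scale = np.where(np.isfinite(hi) & (hi > 0), np.maximum(hi, 1e-12), 1.0)
    zbounds = list(zip(lo / scale, hi / scale))
    eval_points: list[np.ndarray] = []

    use_grad = gradient == "analytic"
    if gradient not in ("analytic", "numeric"):
        raise InvalidInputError(f"unknown gradient mode {gradient!r}")

    def objective(z):
        theta = z * scale
        if track_evals:
            eval_points.append(theta.copy())
        theta = np.maximum(theta, 0.0)
        # The optimizer may probe the F = 0 boundary, where the likelihood
        # is -inf and K/F overflows; floor F so both stay finite there.
        if theta[4] < _F_FLOOR:
            theta[4] = _F_FLOOR
        params = NeuronParams.from_array(theta)
        if use_grad:
            ll, g = joint_log_likelihood_with_gradient(dataset, params)
            if not math.isfinite(ll) or not np.all(np.isfinite(g)):
                return _INFEASIBLE, np.zeros(5)
            return -ll, -g * scale
        ll = joint_log_likelihood(dataset, params)
        if not math.isfinite(ll):
            return _INFEASIBLE
        return -ll

    t0 = time.perf_counter()
    best = None
    best_z0 = None
    starts = []
    for s in range(max(1, multistart)):
        if s == 0 and init is not None:
            starts.append(init.as_array())
        else:
            starts.append(_draw_init(bounds, rng))
    for z0_theta in starts:
        z0 = z0_theta / scale
        res = optimize.minimize(
            objective,
            z0,
            jac=use_grad if use_grad else None,
            method="L-BFGS-B",
            bounds=zbounds,
            options={"maxiter": maxiter, "maxfun": 20 * maxiter, "ftol": ftol, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
            best_z0 = z0_theta
    wall = time.perf_counter() - t0
    if best is None or not math.isfinite(best.fun) or best.fun >= _INFEASIBLE:
        raise EstimationError(
            f"no finite objective found (best status: {getattr(best, 'message', 'n/a')})"
        )
    # F can only hit its zero lower bound on pathological data; from_array
    # would reject F=0, so nudge it to the smallest positive float.
    theta_hat = np.asarray(best.x) * scale
    if theta_hat[4] <= 0:
        theta_hat[4] = np.finfo(float).tiny
    return EstimationResult(
        params=NeuronParams.from_array(theta_hat),
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
        n_iter=int(best.nit),
        n_fev=int(best.nfev),
        init=NeuronParams.from_array(best_z0),
        bounds=bounds,
        wall_seconds=wall,
        message=str(best.message),
        n_starts=len(starts),
        eval_points=eval_points,
    )
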