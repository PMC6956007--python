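"""FitzHugh-Nagumo dynamics with a sigmoid firing-rate readout.

The neuron model is the two-variable FitzHugh-Nagumo (FN) system

    dV/dt = V - d*V^3 - W + I(t)
    dW/dt = c*V + a - b*W

driven by an injected current I(t), with the instantaneous firing rate
read out through a logistic sigmoid of the membrane-potential variable,

    r(t) = F / (1 + exp(-V(t))),

so that five parameters theta = [a, b, c, d, F] fully determine the
stimulus -> rate map.  Time is measured in milliseconds throughout and
rates (r, F) in ms^-1.  Integration is explicit forward Euler on a fixed
grid; the same grid carries the stimulus waveform, the Bernoulli spike
bins and the Riemann sum inside the point-process likelihood, so a single
discretization is shared by the generative model and the estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import _kernels
from .errors import (
    IntegrationDivergedError,
    InvalidInputError,
    InvalidParameterError,
    InvalidStateError,
)

#: Membrane-potential clamp applied before the sigmoid exponentiation.
#: exp(500) is finite in float64, so within the clamp the rate is exact.
V_CLIP = 500.0

#: |V| or |W| beyond this bound is treated as integration blow-up.  The
#: nominal dynamics stay O(10), so 1e6 unambiguously flags a bad parameter
#: draw during optimization.
BLOWUP_BOUND = 1.0e6

__all__ = [
    "NeuronParams",
    "NeuronState",
    "TimeGrid",
    "RateTrajectory",
    "NOMINAL_PARAMS",
    "fn_derivatives",
    "firing_rate",
    "integrate_states",
    "integrate_rate",
    "integrate_rate_batch",
    "V_CLIP",
    "BLOWUP_BOUND",
]

PARAM_NAMES = ("a", "b", "c", "d", "F")


@dataclass(frozen=True)
class NeuronParams:
    """The five-parameter vector theta = [a, b, c, d, F].

    ``a``–``d`` are the dimensionless FN coefficients; ``F`` is the
    maximum firing rate in ms^-1.  All of a, b, c, d must be >= 0 and
    F > 0 (the estimator uses a zero lower bound on every coordinate).
    """

    a: float
    b: float
    c: float
    d: float
    F: float

    def __post_init__(self):
        vals = (self.a, self.b, self.c, self.d, self.F)
        if not all(isinstance(v, (int, float)) and math.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite parameter in {vals}")
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidParameterError("a, b, c, d must be non-negative")
        if self.F <= 0:
            raise InvalidParameterError("F must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.F], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "NeuronParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (5,):
            raise InvalidParameterError("parameter vector must have 5 entries")
        return cls(*(float(v) for v in theta))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_NAMES}


#: Nominal ("true") parameter set used to generate synthetic spike data.
NOMINAL_PARAMS = NeuronParams(a=0.08, b=0.056, c=0.064, d=0.333, F=100.0)


@dataclass(frozen=True)
class NeuronState:
    """Membrane-potential variable V and recovery variable W (dimensionless)."""

    V: float
    W: float

    def __post_init__(self):
        if not (math.isfinite(self.V) and math.isfinite(self.W)):
            raise InvalidStateError(f"non-finite state (V={self.V}, W={self.W})")


@dataclass(frozen=True)
class TimeGrid:
    """Fixed integration/binning grid on a window of duration ``tf`` ms.

    Nodes sit at the left endpoints 0, dt, ..., tf - dt, matching the
    Bernoulli-bin convention: the waveform, the rate and the firing
    probability of bin i are all evaluated at node time i*dt.
    """

    tf: float = 30.0
    dt: float = 0.01

    def __post_init__(self):
        if not (self.dt > 0 and self.tf > 0):
            raise InvalidInputError("tf and dt must be positive")
        ratio = self.tf / self.dt
        if abs(ratio - round(ratio)) > 1e-9 * max(ratio, 1.0):
            raise InvalidInputError(
                f"tf={self.tf} is not an integer multiple of dt={self.dt}"
            )

    @property
    def n_nodes(self) -> int:
        return int(round(self.tf / self.dt))

    @cached_property
    def times(self) -> np.ndarray:
        t = np.arange(self.n_nodes) * self.dt
        t.setflags(write=False)
        return t


@dataclass(frozen=True)
class RateTrajectory:
    """Firing-rate values r(t_i) (ms^-1) on the nodes of a TimeGrid."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.grid.n_nodes,):
            raise InvalidInputError(
                f"rate trajectory has {values.shape} values for "
                f"{self.grid.n_nodes} grid nodes"
            )
        object.__setattr__(self, "values", values)

    @property
    def mean_count(self) -> float:
        """lambda = integral of r over the window (left Riemann sum)."""
        return float(np.sum(self.values) * self.grid.dt)


def fn_derivatives(
    state: NeuronState, params: NeuronParams, stimulus_value: float
) -> tuple[float, float]:
    """Evaluate the FN vector field (dV/dt, dW/dt) at one point."""
    if not math.isfinite(stimulus_value):
        raise InvalidStateError(f"non-finite stimulus value {stimulus_value}")
    V, W = state.V, state.W
    dv = V - params.d * V**3 - W + stimulus_value
    dw = params.c * V + params.a - params.b * W
    return dv, dw


def firing_rate(v, f_max: float):
    """Sigmoid rate map r = F / (1 + exp(-V)), elementwise on arrays.

    V is clamped to [-V_CLIP, V_CLIP] before exponentiation; exp stays
    finite inside the clamp so the rate is unchanged to machine precision
    wherever the clamp is inactive.
    """
    if f_max <= 0:
        raise InvalidParameterError("F must be positive")
    v = np.clip(v, -V_CLIP, V_CLIP)
    return f_max / (1.0 + np.exp(-v))


def integrate_states(
    params: NeuronParams,
    stimulus_waveform: np.ndarray,
    grid: TimeGrid,
    initial_state: NeuronState | None = None,
    method: str = "euler",
) -> tuple[np.ndarray, np.ndarray]:
    """Reference fixed-step integration of one trial; returns (V, W) arrays.

    ``V[i]``/``W[i]`` are the state at node time i*dt, starting from the
    initial state at node 0 (default (0, 0)).  ``method`` is "euler"
    (default, the discretization every other component shares) or "rk4"
    (classical Runge-Kutta with the stimulus held constant over each step,
    available for step-size studies).

    Raises IntegrationDivergedError (naming the step) if |V| or |W|
    exceeds BLOWUP_BOUND or becomes non-finite.
    """
    waveform = np.asarray(stimulus_waveform, dtype=float)
    n = grid.n_nodes
    if waveform.shape != (n,):
        raise InvalidInputError(
            f"waveform has shape {waveform.shape}, expected ({n},)"
        )
    if method not in ("euler", "rk4"):
        raise InvalidInputError(f"unknown method {method!r}")
    state = initial_state or NeuronState(0.0, 0.0)
    v, w = float(state.V), float(state.W)
    a, b, c, d = params.a, params.b, params.c, params.d
    dt = grid.dt
    V = np.empty(n)
    W = np.empty(n)

    def f(v, w, i_ext):
        return v - d * v**3 - w + i_ext, c * v + a - b * w

    for i in range(n):
        V[i] = v
        W[i] = w
        i_ext = waveform[i]
        if method == "euler":
            dv, dw = f(v, w, i_ext)
            v += dt * dv
            w += dt * dw
        else:  # rk4, zero-order-hold stimulus within the step
            k1v, k1w = f(v, w, i_ext)
            k2v, k2w = f(v + 0.5 * dt * k1v, w + 0.5 * dt * k1w, i_ext)
            k3v, k3w = f(v + 0.5 * dt * k2v, w + 0.5 * dt * k2w, i_ext)
            k4v, k4w = f(v + dt * k3v, w + dt * k3w, i_ext)
            v += dt * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0
            w += dt * (k1w + 2 * k2w + 2 * k3w + k4w) / 6.0
        if not (math.isfinite(v) and math.isfinite(w)) or abs(v) > BLOWUP_BOUND or abs(
            w
        ) > BLOWUP_BOUND:
            raise IntegrationDivergedError(i)
    return V, W


def integrate_rate(
    params: NeuronParams,
    stimulus_waveform: np.ndarray,
    grid: TimeGrid,
    initial_state: NeuronState | None = None,
    method: str = "euler",
) -> RateTrajectory:
    """Integrate one trial and map V through the sigmoid rate readout."""
    V, _ = integrate_states(params, stimulus_waveform, grid, initial_state, method)
    return RateTrajectory(grid, firing_rate(V, params.F))


def integrate_rate_batch(
    params: NeuronParams, waveforms: np.ndarray, grid: TimeGrid
) -> np.ndarray:
    """Euler-integrate many trials at once; returns an (M, n) rate matrix.

    All trials start from (V, W) = (0, 0).  This is the fast path used by
    dataset generation; it matches :func:`integrate_rate` trial by trial.
    """
    waveforms = np.ascontiguousarray(waveforms, dtype=float)
    if waveforms.ndim != 2 or waveforms.shape[1] != grid.n_nodes:
        raise InvalidInputError(
            f"waveform matrix shape {waveforms.shape} does not match grid "
            f"({grid.n_nodes} nodes)"
        )
    rates, bad_step = _kernels.integrate_rates(
        params.a, params.b, params.c, params.d, params.F,
        waveforms, grid.dt, V_CLIP, BLOWUP_BOUND,
    )
    if bad_step >= 0:
        raise IntegrationDivergedError(bad_step)
    return rates
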