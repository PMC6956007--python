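"""Spike-train simulation from a rate trajectory.

Two independent simulators of the same inhomogeneous Poisson process:

* local Bernoulli approximation (primary): bin i of width dt fires with
  probability p_i = min(r(t_i) * dt, 1), spikes are reported at the bin's
  left-edge node time;
* thinning (oracle): homogeneous Poisson candidates at a rate bound r*,
  each kept with probability r(t)/r*, the rate linearly interpolated
  between grid nodes.

Both target spike counts with mean lambda = integral of r over the window.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .model import RateTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "bernoulli_fire_probabilities",
    "bernoulli_sample",
    "thinning_sample",
    "superimpose",
    "save_spike_trains_csv",
    "load_spike_trains_csv",
    "spike_trains_to_json",
    "spike_trains_from_json",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) within one trial window [0, window_ms]."""

    times: np.ndarray
    window_ms: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise InvalidInputError("spike times must be a 1-d array")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise InvalidInputError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.window_ms:
                raise InvalidInputError(
                    f"spike times must lie in [0, {self.window_ms}]"
                )
        times = times.copy()
        times.setflags(write=False)
        object.__setattr__(self, "times", times)

    @property
    def count(self) -> int:
        return int(self.times.size)

    def counting_function(self, tau) -> np.ndarray:
        """N(tau) = #{t_k <= tau}."""
        return np.searchsorted(self.times, np.asarray(tau, dtype=float), side="right")


def bernoulli_fire_probabilities(rate: RateTrajectory) -> np.ndarray:
    """Per-bin firing probabilities p_i = min(r(t_i)*dt, 1).

    Logs a warning (the approximation is degraded, not invalid) whenever
    any raw product r*dt exceeds 1.
    """
    p = rate.values * rate.grid.dt
    if np.any(p > 1.0):
        logger.warning(
            "r*dt exceeds 1 in %d bins (max %.3g); Bernoulli approximation degraded",
            int(np.sum(p > 1.0)),
            float(p.max()),
        )
        p = np.minimum(p, 1.0)
    return p


def bernoulli_sample(rate: RateTrajectory, rng: np.random.Generator) -> SpikeTrain:
    """Local-Bernoulli spike train: bin i fires iff p_i > U[0,1] draw."""
    p = bernoulli_fire_probabilities(rate)
    fired = p > rng.random(p.size)
    return SpikeTrain(rate.grid.times[fired], rate.grid.tf)


def thinning_sample(
    rate: RateTrajectory,
    rng: np.random.Generator,
    rate_bound: float | None = None,
) -> SpikeTrain:
    """Thinning sampler: Poisson(r*) candidates kept with probability r(t)/r*.

    ``rate_bound`` defaults to the trajectory maximum (a valid bound since
    the interpolated rate attains its maximum at a node).
    """
    r_star = float(rate.values.max()) if rate_bound is None else float(rate_bound)
    if r_star < rate.values.max():
        raise InvalidInputError("rate_bound must dominate the rate trajectory")
    tf = rate.grid.tf
    if r_star <= 0:
        return SpikeTrain(np.empty(0), tf)
    n_cand = rng.poisson(r_star * tf)
    t = np.sort(rng.uniform(0.0, tf, n_cand))
    r_t = np.interp(t, rate.grid.times, rate.values)
    kept = t[rng.random(n_cand) < r_t / r_star]
    # continuous times: ties have probability zero, but guard the invariant
    return SpikeTrain(np.unique(kept), tf)


def superimpose(trains: list[SpikeTrain]) -> np.ndarray:
    """Merge trains into one long sequence, offsetting train k by k*window.

    All trains must share the same window length.  The result is the
    ascending concatenation; its length is the sum of the counts.
    """
    if not trains:
        return np.empty(0)
    window = trains[0].window_ms
    if any(t.window_ms != window for t in trains):
        raise InvalidInputError("superimpose requires equal window lengths")
    parts = [t.times + k * window for k, t in enumerate(trains)]
    return np.sort(np.concatenate(parts), kind="stable")


# ---------------------------------------------------------------------------
# serialization: CSV (trial_id, spike_time_ms) and JSON; both round-trip


def save_spike_trains_csv(trains: list[SpikeTrain], path) -> None:
    rows = [
        {"trial_id": k, "spike_time_ms": t}
        for k, train in enumerate(trains)
        for t in train.times
    ]
    # %.17g round-trips float64 exactly
    pd.DataFrame(rows, columns=["trial_id", "spike_time_ms"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def load_spike_trains_csv(path, window_ms: float, n_trials: int | None = None) -> list[SpikeTrain]:
    df = pd.read_csv(path, float_precision="round_trip")
    if n_trials is None:
        n_trials = int(df["trial_id"].max()) + 1 if len(df) else 0
    trains = []
    for k in range(n_trials):
        times = df.loc[df["trial_id"] == k, "spike_time_ms"].to_numpy(dtype=float)
        trains.append(SpikeTrain(np.sort(times), window_ms))
    return trains


def spike_trains_to_json(trains: list[SpikeTrain]) -> str:
    window = trains[0].window_ms if trains else 0.0
    return json.dumps(
        {"window_ms": window, "trains": [list(t.times) for t in trains]}
    )


def spike_trains_from_json(s: str) -> list[SpikeTrain]:
    d = json.loads(s)
    return [SpikeTrain(np.asarray(t), d["window_ms"]) for t in d["trains"]]
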