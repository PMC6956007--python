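"""Point-process log-likelihood of spike trains under candidate parameters.

For one trial with rate trajectory r(t) and spikes t_1 < ... < t_K the
inhomogeneous-Poisson log-likelihood is

    l = -integral_0^T r(t) dt + sum_k ln r(t_k),

with the integral taken as a left Riemann sum on the shared grid and
r(t_k) read at the spike's grid node.  The joint log-likelihood over M
independent trials is the sum of per-trial terms, each trial's rate
re-integrated under its own stored stimulus.

Infeasible parameter points (integration blow-up, zero rate at a spike)
yield a -inf sentinel rather than an exception, so bounded optimizers can
reject them gracefully.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from . import _kernels
from .errors import InvalidInputError, SpikeAlignmentError
from .model import (
    BLOWUP_BOUND,
    V_CLIP,
    NeuronParams,
    RateTrajectory,
    TimeGrid,
)
from .sampler import SpikeTrain

__all__ = [
    "Trial",
    "Dataset",
    "spike_nodes",
    "trial_log_likelihood",
    "joint_log_likelihood",
    "joint_log_likelihood_with_gradient",
]


@dataclass(frozen=True)
class Trial:
    """One stimulus + spike-train pair on a shared time grid.

    ``stimulus`` is any object with a ``waveform(grid) -> ndarray`` method
    (a phased-cosine :class:`~fnspike.stimulus.StimulusSpec` for synthetic
    data, a :class:`~fnspike.realdata.SampledStimulus` for recordings).
    """

    stimulus: object
    spikes: SpikeTrain
    grid: TimeGrid
    index: int = 0


def spike_nodes(spikes: SpikeTrain, grid: TimeGrid, align: str = "nearest") -> np.ndarray:
    """Map spike times to grid node indices.

    ``align="nearest"`` (synthetic data) snaps to the nearest node and
    raises SpikeAlignmentError if a spike sits farther than dt/2 from it;
    ``align="floor"`` (real data, arbitrary times) takes the containing bin.
    """
    dt = grid.dt
    n = grid.n_nodes
    t = spikes.times
    if align == "nearest":
        idx = np.rint(t / dt).astype(np.int64)
        off = np.abs(t - idx * dt)
        bad = (off > dt / 2 * (1 + 1e-9)) | (idx < 0) | (idx >= n)
        if np.any(bad):
            k = int(np.argmax(bad))
            raise SpikeAlignmentError(
                f"spike at t={t[k]} ms does not sit on a grid node (dt={dt} ms)"
            )
    elif align == "floor":
        idx = np.floor(t / dt).astype(np.int64)
        idx = np.minimum(idx, n - 1)
        if np.any(idx < 0):
            raise SpikeAlignmentError("negative spike time")
    else:
        raise InvalidInputError(f"unknown alignment mode {align!r}")
    return idx


class Dataset:
    """A set of M independent trials sharing one time grid.

    Parameters
    ----------
    trials : list of Trial
    truth : NeuronParams, optional
        The generating parameters, when known (synthetic data).
    meta : dict, optional
        Provenance (seeds, scenario description).
    align : str
        Spike-to-node alignment mode for all trials ("nearest" or "floor").
    """

    def __init__(self, trials, truth: NeuronParams | None = None,
                 meta: dict | None = None, align: str = "nearest"):
        trials = list(trials)
        if not trials:
            raise InvalidInputError("a dataset needs at least one trial")
        grid = trials[0].grid
        if any((t.grid.tf, t.grid.dt) != (grid.tf, grid.dt) for t in trials):
            raise InvalidInputError("all trials must share tf and dt")
        if align not in ("nearest", "floor"):
            raise InvalidInputError(f"unknown alignment mode {align!r}")
        self.trials = trials
        self.grid = grid
        self.truth = truth
        self.meta = dict(meta or {})
        self.align = align

    def __len__(self) -> int:
        return len(self.trials)

    def __getitem__(self, i) -> Trial:
        return self.trials[i]

    def subset(self, n: int) -> "Dataset":
        """First n trials, sharing waveforms already built where possible."""
        return Dataset(self.trials[:n], truth=self.truth,
                       meta={**self.meta, "subset_of": len(self)}, align=self.align)

    @property
    def total_spikes(self) -> int:
        return sum(t.spikes.count for t in self.trials)

    @cached_property
    def waveforms(self) -> np.ndarray:
        """(M, n) stimulus current matrix, one row per trial."""
        return np.ascontiguousarray(
            np.stack([t.stimulus.waveform(self.grid) for t in self.trials])
        )

    @cached_property
    def _spike_node_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        flat = []
        offsets = np.zeros(len(self.trials) + 1, dtype=np.int64)
        for k, t in enumerate(self.trials):
            nodes = spike_nodes(t.spikes, self.grid, self.align)
            flat.append(np.sort(nodes))
            offsets[k + 1] = offsets[k] + nodes.size
        flat = np.concatenate(flat) if flat else np.empty(0, dtype=np.int64)
        return flat.astype(np.int64), offsets


def trial_log_likelihood(trial: Trial, rate: RateTrajectory, align: str = "nearest") -> float:
    """log p(spikes | rate) for one trial; -inf if a spike's rate is zero."""
    if (rate.grid.tf, rate.grid.dt) != (trial.grid.tf, trial.grid.dt):
        raise InvalidInputError("rate trajectory grid does not match the trial grid")
    nodes = spike_nodes(trial.spikes, trial.grid, align)
    r_k = rate.values[nodes]
    if np.any(r_k <= 0.0):
        return -np.inf
    integral = float(np.sum(rate.values)) * rate.grid.dt
    return -integral + float(np.sum(np.log(r_k)))


def joint_log_likelihood(dataset: Dataset, params: NeuronParams) -> float:
    """Sum of per-trial log-likelihoods at ``params`` (fast kernel path).

    Each trial's rate is re-integrated from its stored stimulus under the
    candidate parameters.  Returns -inf if integration diverges in any
    trial or a spike lands on a zero rate.
    """
    flat, off = dataset._spike_node_arrays
    return float(
        _kernels.joint_loglik(
            params.a, params.b, params.c, params.d, params.F,
            dataset.waveforms, dataset.grid.dt, flat, off, V_CLIP, BLOWUP_BOUND,
        )
    )


def joint_log_likelihood_with_gradient(
    dataset: Dataset, params: NeuronParams
) -> tuple[float, np.ndarray]:
    """Joint log-likelihood and its exact gradient wrt [a, b, c, d, F].

    The gradient differentiates the Euler-discretized objective itself via
    forward sensitivity equations, so it is consistent with
    :func:`joint_log_likelihood` to machine precision.
    """
    flat, off = dataset._spike_node_arrays
    ll, grad = _kernels.joint_loglik_grad(
        params.a, params.b, params.c, params.d, params.F,
        dataset.waveforms, dataset.grid.dt, flat, off, V_CLIP, BLOWUP_BOUND,
    )
    return float(ll), np.asarray(grad)
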