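"""Deterministic synthetic fixtures for tests and demos.

Everything here is generated programmatically from a seed: a baseline
synthetic dataset at the nominal parameters, and a miniature long
recording (stimulus vector + binary spike indicator) shaped like the
real-data pathway's input.  No fixture emulates true blowfly H1
statistics; the long recording exists to exercise the segmentation and
incremental-estimation plumbing without any download.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError
from .experiment import Scenario, generate_dataset
from .likelihood import Dataset
from .model import NOMINAL_PARAMS, NeuronParams, TimeGrid, integrate_rate_batch
from .realdata import RawRecording

__all__ = ["make_baseline_dataset", "make_synthetic_long_recording", "BASELINE_SCENARIO"]

#: Baseline study conditions: Nit=100 trials of 30 ms at 10 us bins,
#: NU=5 components, Amax=100 uA, f0=1/3 kHz.
BASELINE_SCENARIO = Scenario(nit=100, nu=5, amax=100.0, f0=1.0 / 3.0, tf=30.0, dt=0.01)


def make_baseline_dataset(seed: int = 0) -> Dataset:
    """Baseline synthetic dataset at the nominal parameters."""
    return generate_dataset(
        NOMINAL_PARAMS, BASELINE_SCENARIO, np.random.default_rng(seed)
    )


def make_synthetic_long_recording(
    seed: int = 0,
    total_length_ms: float = 60000.0,
    sampling_interval_ms: float = 2.0,
    dt: float = 0.01,
    params: NeuronParams = NOMINAL_PARAMS,
    stimulus_sd: float = 50.0,
    stimulus_hold_ms: float = 2.0,
) -> RawRecording:
    """One continuous synthetic recording in the raw-recording dialect.

    A piecewise-constant Gaussian stimulus (sd ``stimulus_sd``, held for
    ``stimulus_hold_ms``) drives the FN model at ``params``; Bernoulli
    spikes on the dt grid are collapsed to a binary indicator at the
    recording's sampling interval (a bin is 1 if it contains any spike).
    The stored stimulus vector is the recording-rate view of the same
    piecewise-constant signal.
    """
    for name, total, step in (
        ("sampling interval", total_length_ms, sampling_interval_ms),
        ("hold", total_length_ms, stimulus_hold_ms),
        ("dt", sampling_interval_ms, dt),
        ("dt", stimulus_hold_ms, dt),
    ):
        ratio = total / step
        if abs(ratio - round(ratio)) > 1e-9 * max(ratio, 1.0):
            raise InvalidInputError(
                f"{name} must evenly divide its span ({total} / {step})"
            )
    rng = np.random.default_rng(seed)
    n_rec = int(round(total_length_ms / sampling_interval_ms))
    n_hold = int(round(total_length_ms / stimulus_hold_ms))
    n_grid = int(round(total_length_ms / dt))
    levels = rng.normal(0.0, stimulus_sd, n_hold)
    grid_stim = np.repeat(levels, n_grid // n_hold)
    grid = TimeGrid(total_length_ms, dt)
    rates = integrate_rate_batch(params, grid_stim[None, :], grid)[0]
    p = np.minimum(rates * dt, 1.0)
    fired = np.nonzero(p > rng.random(n_grid))[0]
    indicator = np.zeros(n_rec, dtype=np.int8)
    nodes_per_bin = n_grid // n_rec
    indicator[fired // nodes_per_bin] = 1
    rec_stim = grid_stim[:: n_grid // n_rec]
    return RawRecording(rec_stim, indicator, sampling_interval_ms)
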