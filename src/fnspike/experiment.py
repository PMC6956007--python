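"""Repeated-estimation simulation study.

One *scenario* fixes the study conditions: Nit trials per dataset, NU
stimulus components, amplitude Amax, base frequency f0, window Tf, step
dt, and R repetitions.  Each repetition generates a fresh dataset at the
true parameters and runs the bounded ML estimator on it; the summary
records the per-parameter mean and sample standard deviation of the R
estimates (the content of the recovery tables), with failed repetitions
excluded and counted.  Sweeps rerun the experiment over a grid of
scenarios and tabulate means and standard deviations per swept value.

Also provides the relative-error convergence diagnostic

    ER(k) = |theta_hat(k) - theta_hat(k-1)| / |theta_hat(k-1)|

between consecutive cases of an ordered estimate series.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, ExperimentError, InvalidInputError
from .estimator import DEFAULT_BOUNDS, EstimationResult, estimate
from .likelihood import Dataset, Trial
from .model import NeuronParams, TimeGrid, integrate_rate_batch
from .sampler import SpikeTrain
from .stimulus import StimulusSpec, sample_phases

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "ExperimentSummary",
    "generate_dataset",
    "simulate_spike_trains",
    "run_experiment",
    "sweep",
    "summaries_to_tables",
    "relative_error_series",
]

PARAM_COLS = ["a", "b", "c", "d", "F"]


@dataclass(frozen=True)
class Scenario:
    """Study conditions for one repeated-estimation experiment.

    Defaults are the baseline conditions: Nit=100 trials of Tf=30 ms at
    dt=0.01 ms (10 us bins), NU=5 cosine components of amplitude
    Amax=100 uA at base frequency f0=1/3 kHz.
    """

    nit: int = 100
    nu: int = 5
    amax: float = 100.0
    f0: float = 1.0 / 3.0  # kHz
    tf: float = 30.0  # ms
    dt: float = 0.01  # ms
    repetitions: int = 50
    seed: int = 0

    def __post_init__(self):
        if min(self.nit, self.nu, self.repetitions) < 1:
            raise InvalidInputError("nit, nu and repetitions must be positive")
        if not (self.amax >= 0 and self.f0 > 0 and self.tf > 0 and self.dt > 0):
            raise InvalidInputError("amax must be >= 0; f0, tf, dt must be > 0")

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(self.tf, self.dt)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExperimentSummary:
    """Per-parameter mean/std of estimates across repetitions of one scenario."""

    scenario: Scenario
    mean: np.ndarray  # length 5
    std: np.ndarray  # length 5, ddof=1
    raw: pd.DataFrame  # one row per successful repetition
    n_failed: int = 0

    @property
    def effective_repetitions(self) -> int:
        return len(self.raw)

    def mean_dict(self) -> dict:
        return dict(zip(PARAM_COLS, self.mean))

    def std_dict(self) -> dict:
        return dict(zip(PARAM_COLS, self.std))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_dataset(
    truth: NeuronParams, scenario: Scenario, rng=None
) -> Dataset:
    """Nit trials at the true parameters: fresh phases, Euler rate at truth,
    local-Bernoulli spikes.  Each trial consumes its own spawned RNG
    substream, so datasets are exactly replayable from the master seed.
    """
    rng = _as_rng(scenario.seed if rng is None else rng)
    grid = scenario.grid
    streams = rng.spawn(scenario.nit)
    specs = [
        StimulusSpec(
            nu=scenario.nu,
            amax=scenario.amax,
            f0=scenario.f0,
            phases=tuple(sample_phases(scenario.nu, s)),
        )
        for s in streams
    ]
    waveforms = np.stack([spec.waveform(grid) for spec in specs])
    rates = integrate_rate_batch(truth, waveforms, grid)
    trials = []
    for m, (spec, s) in enumerate(zip(specs, streams)):
        p = np.minimum(rates[m] * grid.dt, 1.0)
        fired = p > s.random(grid.n_nodes)
        spikes = SpikeTrain(grid.times[fired], grid.tf)
        trials.append(Trial(stimulus=spec, spikes=spikes, grid=grid, index=m))
    ds = Dataset(
        trials,
        truth=truth,
        meta={"scenario": scenario.to_dict()},
    )
    # the waveforms were already built; seed the cache
    ds.__dict__["waveforms"] = np.ascontiguousarray(waveforms)
    return ds


def simulate_spike_trains(
    params: NeuronParams, stimuli, grid: TimeGrid, rng
) -> list[SpikeTrain]:
    """Bernoulli-sample one spike train per stimulus under ``params``."""
    rng = _as_rng(rng)
    waveforms = np.stack([s.waveform(grid) for s in stimuli])
    rates = integrate_rate_batch(params, waveforms, grid)
    trains = []
    for m in range(len(stimuli)):
        p = np.minimum(rates[m] * grid.dt, 1.0)
        fired = p > rng.random(grid.n_nodes)
        trains.append(SpikeTrain(grid.times[fired], grid.tf))
    return trains


def run_experiment(
    truth: NeuronParams,
    scenario: Scenario,
    estimator_kwargs: dict | None = None,
    rep_seeds=None,
) -> ExperimentSummary:
    """R independent (generate -> estimate) repetitions, summarized.

    ``rep_seeds`` (optional, length R) overrides the per-repetition seeds
    spawned from ``scenario.seed``; passing the same seed twice makes the
    repetitions identical (useful for degenerate-replication checks).
    Failed repetitions are logged and excluded, never retried; if fewer
    than 2 succeed, ExperimentError is raised.
    """
    R = scenario.repetitions
    if R < 2:
        raise InvalidInputError("repetitions must be >= 2 for a std to exist")
    estimator_kwargs = dict(estimator_kwargs or {})
    if rep_seeds is not None:
        if len(rep_seeds) != R:
            raise InvalidInputError("rep_seeds must have one entry per repetition")
        seed_seqs = [np.random.SeedSequence(s) for s in rep_seeds]
    else:
        seed_seqs = np.random.SeedSequence(scenario.seed).spawn(R)
    rows = []
    n_failed = 0
    for rep, ss in enumerate(seed_seqs):
        ss_data, ss_init = ss.spawn(2)
        ds = generate_dataset(truth, scenario, np.random.default_rng(ss_data))
        try:
            res = estimate(ds, seed=np.random.default_rng(ss_init), **estimator_kwargs)
        except EstimationError as e:
            logger.warning("repetition %d failed: %s", rep, e)
            n_failed += 1
            continue
        rows.append(
            {
                "rep": rep,
                **dict(zip(PARAM_COLS, res.params.as_array())),
                "log_likelihood": res.log_likelihood,
                "converged": res.converged,
                "n_iter": res.n_iter,
            }
        )
    raw = pd.DataFrame(rows)
    if len(raw) < 2:
        raise ExperimentError(
            f"only {len(raw)} of {R} repetitions produced estimates"
        )
    theta = raw[PARAM_COLS].to_numpy()
    return ExperimentSummary(
        scenario=scenario,
        mean=theta.mean(axis=0),
        std=theta.std(axis=0, ddof=1),
        raw=raw,
        n_failed=n_failed,
    )


def sweep(
    truth: NeuronParams,
    scenarios,
    estimator_kwargs: dict | None = None,
) -> list[ExperimentSummary | None]:
    """Run one experiment per scenario; per-scenario failures yield None."""
    scenarios = list(scenarios)
    if not scenarios:
        raise InvalidInputError("scenario grid is empty")
    out = []
    for sc in scenarios:
        try:
            out.append(run_experiment(truth, sc, estimator_kwargs))
        except ExperimentError as e:
            logger.warning("scenario %s failed: %s", sc, e)
            out.append(None)
    return out


def summaries_to_tables(
    summaries, vary: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and std tables (rows: swept value, columns: a..F)."""
    mean_rows, std_rows, index = [], [], []
    for s in summaries:
        if s is None:
            continue
        index.append(getattr(s.scenario, vary))
        mean_rows.append(s.mean)
        std_rows.append(s.std)
    mean_df = pd.DataFrame(mean_rows, index=pd.Index(index, name=vary), columns=PARAM_COLS)
    std_df = pd.DataFrame(std_rows, index=pd.Index(index, name=vary), columns=PARAM_COLS)
    return mean_df, std_df


def relative_error_series(estimates, labels=None) -> pd.DataFrame:
    """ER(k) = |theta(k) - theta(k-1)| / |theta(k-1)| per parameter column.

    ``estimates`` is an (n_cases, n_params) array or DataFrame ordered by
    case; the series starts at the second case.  A zero previous estimate
    yields Inf unless the estimate did not change (then 0).
    """
    if isinstance(estimates, pd.DataFrame):
        values = estimates.to_numpy(dtype=float)
        columns = list(estimates.columns)
        if labels is None:
            labels = list(estimates.index)
    else:
        values = np.asarray(estimates, dtype=float)
        columns = PARAM_COLS[: values.shape[1]] if values.ndim == 2 else None
    if values.ndim != 2 or values.shape[0] < 2:
        raise InvalidInputError("need at least two ordered cases")
    prev = values[:-1]
    diff = np.abs(np.diff(values, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        er = diff / np.abs(prev)
    er[(prev == 0) & (diff == 0)] = 0.0
    er[(prev == 0) & (diff != 0)] = np.inf
    idx = labels[1:] if labels is not None else np.arange(1, values.shape[0])
    return pd.DataFrame(er, index=pd.Index(idx, name="case"), columns=columns)
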