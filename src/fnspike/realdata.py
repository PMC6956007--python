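"""Long-recording pathway: load, segment, and incrementally estimate.

A raw recording is a stimulus vector plus a binary spike-indicator vector
sampled at a fixed interval (the blowfly H1 dataset ships this shape as a
MATLAB workspace file; plain CSV and NPZ dialects are supported for
fixtures).  The recording is cut into equal fixed-length segments, each
treated as an independent trial whose recorded stimulus segment is used
directly as the injected current I(t) (zero-order hold onto the
integration grid; an optional scale factor converts recorded stimulus
units into model current units).  Incremental estimation then fits the
model on growing prefixes of the segment list and reports the
relative-error series between consecutive sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, RecordingFormatError
from .estimator import estimate
from .experiment import PARAM_COLS, relative_error_series
from .likelihood import Dataset, Trial
from .model import TimeGrid
from .sampler import SpikeTrain

__all__ = [
    "RawRecording",
    "SampledStimulus",
    "SegmentedRecording",
    "load_recording",
    "save_recording_csv",
    "segment_recording",
    "incremental_estimation",
]


@dataclass(frozen=True)
class RawRecording:
    """Stimulus vector + binary spike indicator at a fixed sampling interval."""

    stimulus: np.ndarray
    indicator: np.ndarray
    sampling_interval_ms: float

    def __post_init__(self):
        stim = np.asarray(self.stimulus, dtype=float).ravel()
        ind = np.asarray(self.indicator).ravel()
        if stim.size != ind.size:
            raise RecordingFormatError(
                f"stimulus ({stim.size}) and indicator ({ind.size}) lengths differ"
            )
        if not np.isin(ind, (0, 1)).all():
            raise RecordingFormatError("indicator must contain only 0 and 1")
        if not self.sampling_interval_ms > 0:
            raise RecordingFormatError("sampling interval must be positive")
        object.__setattr__(self, "stimulus", stim)
        object.__setattr__(self, "indicator", ind.astype(np.int8))

    @property
    def duration_ms(self) -> float:
        return self.stimulus.size * self.sampling_interval_ms

    @property
    def spike_times(self) -> np.ndarray:
        """Spike times = indicator positions x sampling interval (ms)."""
        return np.nonzero(self.indicator)[0] * self.sampling_interval_ms


class SampledStimulus:
    """Recorded stimulus segment, resampled to a grid by zero-order hold."""

    def __init__(self, values: np.ndarray, sample_interval_ms: float, scale: float = 1.0):
        self.values = np.asarray(values, dtype=float)
        self.sample_interval_ms = float(sample_interval_ms)
        self.scale = float(scale)

    def waveform(self, grid: TimeGrid) -> np.ndarray:
        idx = np.floor(grid.times / self.sample_interval_ms).astype(int)
        idx = np.minimum(idx, self.values.size - 1)
        return self.scale * self.values[idx]


@dataclass(frozen=True)
class SegmentedRecording:
    """Equal-length (stimulus segment, spike train) pairs from one recording."""

    segment_length_ms: float
    sampling_interval_ms: float
    segments: tuple  # of (SampledStimulus, SpikeTrain)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def stimuli(self) -> list:
        return [s for s, _ in self.segments]

    @property
    def trains(self) -> list:
        return [t for _, t in self.segments]


def load_recording(
    path,
    stimulus_field: str = "stim",
    indicator_field: str = "rho",
    sampling_interval_ms: float = 2.0,
) -> RawRecording:
    """Read a raw recording from .mat, .npz or .csv.

    * ``.mat``: MATLAB workspace with arrays named by the two field args
      (defaults match the published blowfly H1 file).
    * ``.npz``: arrays ``stimulus`` and ``indicator``, optional scalar
      ``sampling_interval_ms`` overriding the argument.
    * ``.csv``: columns ``stimulus`` and ``indicator``.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingFormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".mat":
        from scipy.io import loadmat

        raw = loadmat(path)
        for f in (stimulus_field, indicator_field):
            if f not in raw:
                raise RecordingFormatError(f"missing field {f!r} in {path.name}")
        stim, ind = raw[stimulus_field], raw[indicator_field]
    elif suffix == ".npz":
        raw = np.load(path)
        for f in ("stimulus", "indicator"):
            if f not in raw:
                raise RecordingFormatError(f"missing array {f!r} in {path.name}")
        stim, ind = raw["stimulus"], raw["indicator"]
        if "sampling_interval_ms" in raw:
            sampling_interval_ms = float(raw["sampling_interval_ms"])
    elif suffix == ".csv":
        df = pd.read_csv(path)
        for f in ("stimulus", "indicator"):
            if f not in df.columns:
                raise RecordingFormatError(f"missing column {f!r} in {path.name}")
        stim, ind = df["stimulus"].to_numpy(), df["indicator"].to_numpy()
    else:
        raise RecordingFormatError(f"unsupported recording format {suffix!r}")
    return RawRecording(stim, ind, sampling_interval_ms)


def save_recording_csv(recording: RawRecording, path) -> None:
    pd.DataFrame(
        {"stimulus": recording.stimulus, "indicator": recording.indicator}
    ).to_csv(path, index=False)


def segment_recording(recording: RawRecording, segment_length_ms: float) -> SegmentedRecording:
    """Cut into floor(duration/length) equal segments; remainder dropped.

    Spike times are re-based to segment-local time; the stimulus is sliced
    identically, so concatenating segments reproduces the kept span.
    """
    if segment_length_ms <= 0:
        raise InvalidInputError("segment length must be positive")
    interval = recording.sampling_interval_ms
    per_seg = segment_length_ms / interval
    if abs(per_seg - round(per_seg)) > 1e-9 * max(per_seg, 1.0):
        raise InvalidInputError(
            "segment length must be an integer number of sampling intervals"
        )
    per_seg = int(round(per_seg))
    n_seg = recording.stimulus.size // per_seg
    if n_seg < 1:
        raise InvalidInputError("recording shorter than one segment")
    segments = []
    for k in range(n_seg):
        sl = slice(k * per_seg, (k + 1) * per_seg)
        stim = SampledStimulus(recording.stimulus[sl], interval)
        local_idx = np.nonzero(recording.indicator[sl])[0]
        train = SpikeTrain(local_idx * interval, segment_length_ms)
        segments.append((stim, train))
    return SegmentedRecording(
        segment_length_ms=segment_length_ms,
        sampling_interval_ms=interval,
        segments=tuple(segments),
    )


def incremental_estimation(
    segments: SegmentedRecording,
    sample_sizes,
    dt: float = 0.01,
    stimulus_scale: float = 1.0,
    estimator_kwargs: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate on growing prefixes of the segment list.

    For each size N in ``sample_sizes`` (ascending, each <= number of
    segments) the first N segments form the dataset; spike times are
    floor-aligned to the integration grid.  Returns (estimates, errors):
    per-size parameter estimates indexed by N, and the relative-error
    series ER(k) between consecutive sizes.  A failed estimation is
    recorded as a NaN row and excluded from the error series.
    """
    sizes = [int(n) for n in sample_sizes]
    if sorted(sizes) != sizes or len(sizes) < 1:
        raise InvalidInputError("sample sizes must be ascending")
    if sizes[-1] > len(segments):
        raise InvalidInputError(
            f"largest sample size {sizes[-1]} exceeds segment count {len(segments)}"
        )
    estimator_kwargs = dict(estimator_kwargs or {})
    grid = TimeGrid(segments.segment_length_ms, dt)
    trials = []
    for m, (stim, train) in enumerate(segments.segments[: sizes[-1]]):
        stim = SampledStimulus(stim.values, stim.sample_interval_ms, scale=stimulus_scale)
        trials.append(Trial(stimulus=stim, spikes=train, grid=grid, index=m))
    full = Dataset(trials, align="floor")
    seed_seqs = np.random.SeedSequence(seed).spawn(len(sizes))
    rows = []
    for n, ss in zip(sizes, seed_seqs):
        sub = Dataset(full.trials[:n], align="floor")
        sub.__dict__["waveforms"] = full.waveforms[:n]
        try:
            res = estimate(sub, seed=np.random.default_rng(ss), **estimator_kwargs)
            rows.append(res.params.as_array())
        except Exception:  # noqa: BLE001 - estimation failures recorded per size
            rows.append(np.full(5, np.nan))
    estimates = pd.DataFrame(rows, index=pd.Index(sizes, name="Nit"), columns=PARAM_COLS)
    ok = estimates.dropna()
    errors = relative_error_series(ok) if len(ok) >= 2 else pd.DataFrame(columns=PARAM_COLS)
    return estimates, errors
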