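"""Dataset and result (de)serialization.

A dataset directory holds three plain-text files:

* ``spikes.csv``     — columns trial_id, spike_time_ms
* ``stimuli.json``   — list of stimulus specs (NU, Amax_uA, f0_kHz, phases_rad)
* ``meta.json``      — tf_ms, dt_ms, align, optional truth and provenance
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import InvalidInputError
from .likelihood import Dataset, Trial
from .model import NeuronParams, TimeGrid
from .sampler import load_spike_trains_csv, save_spike_trains_csv
from .stimulus import StimulusSpec

__all__ = ["save_dataset", "load_dataset"]


def save_dataset(dataset: Dataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_spike_trains_csv([t.spikes for t in dataset.trials], out / "spikes.csv")
    specs = []
    for t in dataset.trials:
        if not isinstance(t.stimulus, StimulusSpec):
            raise InvalidInputError(
                "only phased-cosine stimulus datasets serialize to a dataset directory"
            )
        specs.append(t.stimulus.to_dict())
    (out / "stimuli.json").write_text(json.dumps(specs))
    meta = {
        "tf_ms": dataset.grid.tf,
        "dt_ms": dataset.grid.dt,
        "align": dataset.align,
        "truth": dataset.truth.to_dict() if dataset.truth else None,
        **dataset.meta,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def load_dataset(in_dir) -> Dataset:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    grid = TimeGrid(meta["tf_ms"], meta["dt_ms"])
    specs = [StimulusSpec.from_dict(d) for d in json.loads((src / "stimuli.json").read_text())]
    trains = load_spike_trains_csv(src / "spikes.csv", grid.tf, n_trials=len(specs))
    trials = [
        Trial(stimulus=s, spikes=t, grid=grid, index=k)
        for k, (s, t) in enumerate(zip(specs, trains))
    ]
    truth = NeuronParams(**meta["truth"]) if meta.get("truth") else None
    extra = {k: v for k, v in meta.items() if k not in ("tf_ms", "dt_ms", "align", "truth")}
    return Dataset(trials, truth=truth, meta=extra, align=meta.get("align", "nearest"))
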