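"""Distributional goodness-of-fit via two-sample KS tests on ISIs.

Reference spike trains (measured segments, or an independent simulation)
and model-simulated trains are each superimposed — train k offset by
k x window — into one long sequence; interspike intervals are taken on the
merged sequence and compared with a two-sample Kolmogorov–Smirnov test
(asymptotic p-value).  The p-value is tracked as the number of
superimposed segments grows.

Note the superimposition happens *before* ISI extraction, so the gaps
between consecutive segments contribute intervals; this mirrors the
estimation-study procedure rather than a statistically purer per-segment
pooling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .experiment import simulate_spike_trains
from .model import NeuronParams, TimeGrid
from .sampler import superimpose

logger = logging.getLogger(__name__)

__all__ = ["interspike_intervals", "ks_two_sample", "pvalue_vs_samples"]


def interspike_intervals(sequence) -> np.ndarray:
    """First differences of an ordered spike sequence; empty if < 2 spikes."""
    t = np.asarray(sequence, dtype=float)
    if t.size < 2:
        logger.warning("fewer than 2 spikes; ISI sample is empty")
        return np.empty(0)
    return np.diff(t)


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample KS statistic (sup ECDF distance) and asymptotic p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def pvalue_vs_samples(
    reference_trains,
    stimuli,
    params: NeuronParams,
    grid: TimeGrid,
    sample_counts,
    rng,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int | None]:
    """KS p-value between reference and model ISIs vs. segment count.

    For each count n, the first n reference trains and the first n
    model-simulated trains (one Bernoulli simulation per stimulus under
    ``params``) are superimposed, ISIs extracted from each merged
    sequence, and the two ISI samples KS-tested.

    Returns the (n, statistic, pvalue) curve and the first n whose p-value
    exceeds ``alpha`` (None if the curve never crosses it).
    """
    counts = [int(n) for n in sample_counts]
    if sorted(counts) != counts or not counts:
        raise InvalidInputError("sample counts must be ascending and non-empty")
    reference_trains = list(reference_trains)
    stimuli = list(stimuli)
    if counts[-1] > min(len(reference_trains), len(stimuli)):
        raise InvalidInputError("largest count exceeds available segments")
    model_trains = simulate_spike_trains(params, stimuli[: counts[-1]], grid, rng)
    rows = []
    first_passing = None
    for n in counts:
        ref_isi = interspike_intervals(superimpose(reference_trains[:n]))
        mod_isi = interspike_intervals(superimpose(model_trains[:n]))
        stat, p = ks_two_sample(ref_isi, mod_isi)
        rows.append({"n_segments": n, "statistic": stat, "pvalue": p})
        if first_passing is None and p > alpha:
            first_passing = n
    return pd.DataFrame(rows), first_passing
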