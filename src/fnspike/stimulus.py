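"""Phased-cosine Fourier-series stimuli.

A trial's injected current is

    I(t) = sum_{n=1..NU} Amax * cos(2*pi*f0*n*t + phi_n),

with a common component amplitude Amax (uA), base frequency f0 (kHz, so
that 2*pi*f0*n*t is dimensionless with t in ms) and per-trial phases phi_n
drawn i.i.d. uniform on [-pi, pi].  The phases are the only randomness:
they are drawn once per trial and stored with the trial record, because
the likelihood must re-integrate the model under the same stimulus that
elicited the spikes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InvalidStimulusError
from .model import TimeGrid

__all__ = ["StimulusSpec", "sample_phases", "evaluate_stimulus", "random_stimulus"]


@dataclass(frozen=True)
class StimulusSpec:
    """One trial's stimulus: component count, amplitude, base frequency, phases."""

    nu: int
    amax: float
    f0: float  # kHz
    phases: tuple  # radians, length nu, each in [-pi, pi]

    def __post_init__(self):
        if int(self.nu) != self.nu or self.nu < 1:
            raise InvalidStimulusError(f"NU must be a positive integer, got {self.nu}")
        if not self.amax >= 0:
            raise InvalidStimulusError(f"Amax must be >= 0, got {self.amax}")
        if not self.f0 > 0:
            raise InvalidStimulusError(f"f0 must be > 0, got {self.f0}")
        phases = tuple(float(p) for p in np.atleast_1d(np.asarray(self.phases, dtype=float)))
        if len(phases) != self.nu:
            raise InvalidStimulusError(
                f"expected {self.nu} phases, got {len(phases)}"
            )
        if any(abs(p) > np.pi * (1 + 1e-12) for p in phases):
            raise InvalidStimulusError("phases must lie in [-pi, pi]")
        object.__setattr__(self, "nu", int(self.nu))
        object.__setattr__(self, "phases", phases)

    def waveform(self, grid: TimeGrid) -> np.ndarray:
        """Evaluate I(t) on the grid nodes 0, dt, ..., tf - dt."""
        t = grid.times
        n = np.arange(1, self.nu + 1)
        args = 2.0 * np.pi * self.f0 * np.outer(n, t) + np.asarray(self.phases)[:, None]
        return self.amax * np.cos(args).sum(axis=0)

    def to_dict(self) -> dict:
        return {
            "NU": self.nu,
            "Amax_uA": self.amax,
            "f0_kHz": self.f0,
            "phases_rad": list(self.phases),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        return cls(nu=d["NU"], amax=d["Amax_uA"], f0=d["f0_kHz"], phases=d["phases_rad"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "StimulusSpec":
        return cls.from_dict(json.loads(s))


def sample_phases(nu: int, rng: np.random.Generator) -> np.ndarray:
    """Draw NU i.i.d. phases uniform on [-pi, pi]."""
    if nu < 1:
        raise InvalidStimulusError(f"NU must be >= 1, got {nu}")
    return rng.uniform(-np.pi, np.pi, int(nu))


def evaluate_stimulus(spec: StimulusSpec, grid: TimeGrid) -> np.ndarray:
    """Per-node current waveform for a stimulus spec (pure function)."""
    return spec.waveform(grid)


def random_stimulus(
    nu: int, amax: float, f0: float, rng: np.random.Generator
) -> StimulusSpec:
    """Convenience: draw fresh phases and build the spec."""
    return StimulusSpec(nu=nu, amax=amax, f0=f0, phases=tuple(sample_phases(nu, rng)))
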