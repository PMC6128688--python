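"""Core containers for patch-clamp current traces.

A :class:`Sweep` is the atom of every trace analysis in this package: one
recorded or simulated membrane-current time series (pA, inward negative by
convention) together with its sampling rate, holding potential and stimulus
annotation.  A :class:`SweepSet` is an ordered collection of sweeps sharing a
sampling rate, with set-level metadata (simulation preset, seed, ground-truth
parameters when synthetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np

__all__ = ["Sweep", "SweepSet"]


@dataclass
class Sweep:
    """One current trace with sampling and stimulus metadata.

    Parameters
    ----------
    samples : ndarray
        Membrane current in pA; inward current is negative.
    fs : float
        Sampling rate in Hz.
    v_hold : float
        Holding potential in mV.
    stim_onset, stim_duration : float
        Stimulus timing in ms relative to the start of the sweep.
    stim_amplitude : float
        Stimulus amplitude: probe depth in µm (poke) or pressure in mmHg.
    stim_kind : str
        ``"poke"`` or ``"pressure"``.
    sweep_id : str
        Identifier, unique within a :class:`SweepSet`.
    annotations : dict
        Free-form metadata, including ground truth for simulated sweeps.
    """

    samples: np.ndarray
    fs: float
    v_hold: float
    stim_onset: float
    stim_duration: float
    stim_amplitude: float = 0.0
    stim_kind: str = "poke"
    sweep_id: str = "sweep"
    annotations: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not 0 <= self.stim_onset < self.duration_ms:
            raise ValueError(
                f"stim_onset {self.stim_onset} ms outside sweep of "
                f"{self.duration_ms:.3f} ms"
            )
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms (implicit, from the sampling rate)."""
        return np.arange(self.n_samples) * (1000.0 / self.fs)

    def index_at(self, t_ms: float) -> int:
        """Index of the sample closest to time ``t_ms``."""
        return int(round(t_ms * self.fs / 1000.0))

    def slice_ms(self, t0: float, t1: float) -> np.ndarray:
        """Samples in the half-open time window ``[t0, t1)`` ms."""
        if t1 <= t0:
            raise ValueError(f"empty window [{t0}, {t1}) ms")
        i0 = max(self.index_at(t0), 0)
        i1 = min(self.index_at(t1), self.n_samples)
        if i1 <= i0:
            raise ValueError(f"window [{t0}, {t1}) ms contains no samples")
        return self.samples[i0:i1]


@dataclass
class SweepSet:
    """Ordered collection of sweeps sharing a sampling rate."""

    sweeps: list[Sweep]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sweeps:
            fs0 = self.sweeps[0].fs
            for sw in self.sweeps:
                if sw.fs != fs0:
                    raise ValueError("all sweeps in a SweepSet must share fs")
            ids = [sw.sweep_id for sw in self.sweeps]
            if len(set(ids)) != len(ids):
                raise ValueError("sweep ids must be unique within a SweepSet")

    @property
    def fs(self) -> float:
        if not self.sweeps:
            raise ValueError("empty SweepSet has no sampling rate")
        return self.sweeps[0].fs

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self) -> Iterator[Sweep]:
        return iter(self.sweeps)

    def __getitem__(self, i: int) -> Sweep:
        return self.sweeps[i]
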