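"""Sweep-container I/O.

The primary container is a chunked hierarchical (HDF5) file: one group per
sweep holding a ``current_pA`` dataset plus the sampling and stimulus
metadata as attributes, and set-level metadata (preset, seed, ground truth)
as root attributes.  Times are implicit (sampling rate + index), keeping the
container compact.  A delimited-text fallback (columns ``time_s``,
``current_pA``, ``stimulus``) is supported for single sweeps, carrying
explicit times for interoperability.

The current sign convention — inward current negative — is fixed at this
boundary: containers always store signed pA.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .sweeps import Sweep, SweepSet

__all__ = [
    "write_sweepset",
    "read_sweepset",
    "write_sweep_csv",
    "read_sweep_csv",
    "write_run_record",
]

_SCHEMA_VERSION = 1
_REQUIRED_ATTRS = ("fs", "v_hold", "stim_onset", "stim_duration", "stim_amplitude")


def write_sweepset(sweepset: SweepSet, path: str | Path) -> Path:
    """Write a :class:`SweepSet` to an HDF5 container (lossless round trip)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        f.attrs["container"] = "mechanopatch-sweepset"
        f.attrs["metadata_json"] = json.dumps(sweepset.metadata, default=str)
        for k, sweep in enumerate(sweepset):
            grp = f.create_group(f"sweep_{k:04d}")
            grp.create_dataset("current_pA", data=sweep.samples, dtype="f8")
            grp.attrs["fs"] = sweep.fs
            grp.attrs["v_hold"] = sweep.v_hold
            grp.attrs["stim_onset"] = sweep.stim_onset
            grp.attrs["stim_duration"] = sweep.stim_duration
            grp.attrs["stim_amplitude"] = sweep.stim_amplitude
            grp.attrs["stim_kind"] = sweep.stim_kind
            grp.attrs["sweep_id"] = sweep.sweep_id
            grp.attrs["annotations_json"] = json.dumps(
                sweep.annotations, default=str
            )
    return path


def read_sweepset(path: str | Path) -> SweepSet:
    """Read a :class:`SweepSet` from an HDF5 container.

    Missing required fields raise an error naming the field rather than
    guessing a value.
    """
    path = Path(path)
    sweeps = []
    with h5py.File(path, "r") as f:
        metadata = json.loads(f.attrs.get("metadata_json", "{}"))
        for name in sorted(k for k in f.keys() if k.startswith("sweep_")):
            grp = f[name]
            if "current_pA" not in grp:
                raise ValueError(f"{path}:{name} is missing dataset 'current_pA'")
            for attr in _REQUIRED_ATTRS:
                if attr not in grp.attrs:
                    raise ValueError(
                        f"{path}:{name} is missing required attribute {attr!r}"
                    )
            sweeps.append(
                Sweep(
                    samples=np.asarray(grp["current_pA"][...], dtype=float),
                    fs=float(grp.attrs["fs"]),
                    v_hold=float(grp.attrs["v_hold"]),
                    stim_onset=float(grp.attrs["stim_onset"]),
                    stim_duration=float(grp.attrs["stim_duration"]),
                    stim_amplitude=float(grp.attrs["stim_amplitude"]),
                    stim_kind=str(grp.attrs.get("stim_kind", "poke")),
                    sweep_id=str(grp.attrs.get("sweep_id", name)),
                    annotations=json.loads(grp.attrs.get("annotations_json", "{}")),
                )
            )
    return SweepSet(sweeps=sweeps, metadata=metadata)


def write_sweep_csv(sweep: Sweep, path: str | Path) -> Path:
    """Write a single sweep as delimited text (time_s, current_pA, stimulus).

    Stimulus metadata travels in ``#``-prefixed header lines so the text
    dialect round-trips too.
    """
    path = Path(path)
    from .gating import StimulusProtocol  # local import to avoid a cycle

    protocol = StimulusProtocol(
        kind=sweep.stim_kind,
        onset=sweep.stim_onset,
        duration=sweep.stim_duration,
        amplitude=sweep.stim_amplitude,
    )
    stim = protocol.waveform(sweep.times_ms, t_end=sweep.duration_ms)
    header = [
        f"# v_hold_mV={sweep.v_hold}",
        f"# stim_onset_ms={sweep.stim_onset}",
        f"# stim_duration_ms={sweep.stim_duration}",
        f"# stim_amplitude={sweep.stim_amplitude}",
        f"# stim_kind={sweep.stim_kind}",
        f"# sweep_id={sweep.sweep_id}",
    ]
    df = pd.DataFrame(
        {
            "time_s": sweep.times_ms / 1000.0,
            "current_pA": sweep.samples,
            "stimulus": stim,
        }
    )
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_sweep_csv(path: str | Path) -> Sweep:
    """Read a single sweep from the text dialect; ``fs`` is inferred from the
    time column."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ValueError(f"{path} is missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples to infer the sampling rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    fs = 1.0 / float(np.median(dt))
    return Sweep(
        samples=df["current_pA"].to_numpy(dtype=float),
        fs=fs,
        v_hold=float(meta.get("v_hold_mV", 0.0)),
        stim_onset=float(meta.get("stim_onset_ms", 0.0)),
        stim_duration=float(meta.get("stim_duration_ms", t[-1] * 1000.0 or 1.0)),
        stim_amplitude=float(meta.get("stim_amplitude", 0.0)),
        stim_kind=meta.get("stim_kind", "poke"),
        sweep_id=meta.get("sweep_id", path.stem),
    )


def write_run_record(path: str | Path, config: dict[str, Any]) -> Path:
    """Write a machine-readable JSON record of the parameters and seed that
    produced an output artifact."""
    path = Path(path)
    record = dict(config)
    try:
        from importlib.metadata import version

        record.setdefault("package_version", version("mechanopatch"))
    except Exception:
        record.setdefault("package_version", "unknown")
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path
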