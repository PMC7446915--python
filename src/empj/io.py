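"""HDF5 persistence for synthesized networks and trajectories.

Networks round-trip losslessly (float64 weights, time constant, specs,
seeds); datasets are written with ``track_times=False`` so repeated
saves of the same network are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .dynamics import DriftSpec
from .manifolds import RingSpec
from .simulate import Trajectory
from .synthesis import RNN

__all__ = ["save_network", "load_network", "save_trajectory", "FormatError"]

_FORMAT_VERSION = 1


class FormatError(RuntimeError):
    """Raised when a network file is missing required fields or corrupt."""


def save_network(rnn: RNN, path: str | Path) -> None:
    """Write a network (weights, tau, input vector, metadata) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["metadata"] = json.dumps(rnn.metadata, sort_keys=True)
        f.create_dataset("W", data=np.asarray(rnn.weights, dtype=np.float64), track_times=False)
        f.create_dataset("tau", data=float(rnn.tau), track_times=False)
        if rnn.input_vector is not None:
            f.create_dataset(
                "input_vector",
                data=np.asarray(rnn.input_vector, dtype=np.float64),
                track_times=False,
            )


def load_network(path: str | Path) -> RNN:
    """Read a network written by :func:`save_network`."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if "W" not in f or "tau" not in f:
                raise FormatError(f"{path}: not a network file (missing W or tau)")
            version = int(f.attrs.get("format_version", -1))
            if version != _FORMAT_VERSION:
                raise FormatError(f"{path}: unsupported format version {version}")
            weights = f["W"][()]
            tau = float(f["tau"][()])
            input_vector = f["input_vector"][()] if "input_vector" in f else None
            metadata = json.loads(f.attrs.get("metadata", "{}"))
    except OSError as exc:
        raise FormatError(f"{path}: unreadable or corrupt HDF5 file ({exc})") from exc
    return RNN(weights=weights, tau=tau, input_vector=input_vector, metadata=metadata)


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory (/times, /states) to HDF5 with gzip compression."""
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("times", data=traj.times, track_times=False)
        f.create_dataset(
            "states", data=traj.states, compression="gzip", track_times=False
        )


def ring_from_metadata(metadata: dict) -> RingSpec:
    """Rebuild the RingSpec recorded in a network's metadata."""
    if "ring_spec" not in metadata:
        raise FormatError("network metadata carries no ring specification")
    return RingSpec.from_dict(metadata["ring_spec"])


def drift_from_metadata(metadata: dict) -> DriftSpec:
    """Rebuild the DriftSpec recorded in a network's metadata."""
    if "drift_spec" not in metadata:
        raise FormatError("network metadata carries no drift specification")
    return DriftSpec.from_dict(metadata["drift_spec"])
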