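"""Readers/writers for the package's artifacts.

CSV is the canonical tabular format; trajectories additionally go to a
portable ``.npz`` container (one array per field plus sample times) and, in
1D, to a kymograph CSV whose rows are time samples and columns grid nodes.
Every output directory also receives the fully resolved run configuration
(YAML) and the package version, so a run can be reproduced bit-for-bit from
its own outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .solvers import Trajectory

__all__ = [
    "write_config",
    "write_trajectory",
    "write_kymograph_csv",
    "load_trajectory",
]


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_config(outdir: Path, config) -> Path:
    """Echo the resolved configuration and package version into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "config.yaml"
    payload = dict(version=__version__, config=_plain(config))
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def write_trajectory(path: Path, traj: Trajectory) -> None:
    """Portable array dump: times, per-field arrays, amplitudes."""
    arrays = dict(
        times=traj.times,
        amplitudes=traj.amplitudes,
    )
    for i in range(traj.fields.shape[1]):
        arrays[f"field_{i}"] = traj.fields[:, i]
    np.savez_compressed(path, **arrays)


def load_trajectory(path: Path) -> Trajectory:
    with np.load(path) as data:
        names = sorted(k for k in data.files if k.startswith("field_"))
        fields = np.stack([data[k] for k in names], axis=1)
        return Trajectory(
            times=data["times"],
            fields=fields,
            amplitudes=data["amplitudes"],
        )


def write_kymograph_csv(path: Path, traj: Trajectory) -> None:
    """u over (time, space) as CSV: first column t, then one column per node."""
    kymo = traj.kymograph()
    if kymo.ndim != 2:
        raise ValueError("kymograph CSV export is for 1D trajectories")
    out = np.column_stack([traj.times, kymo])
    header = "t," + ",".join(f"x{j}" for j in range(kymo.shape[1]))
    np.savetxt(path, out, delimiter=",", header=header, comments="")
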