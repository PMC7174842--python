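"""Persistence: HDF5 trajectories, JSON/CSV metrics, CSV mask export.

Layout of a trajectory file::

    /times                  (n,) float64
    /snapshots/<i>/<field>  (ny, nx) float64, one group per snapshot
    /masks/<i>/omega|committed|crescent
    attrs: seed, config (JSON string), config_hash, version
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import DomainMasks
from .solver import Trajectory


def save_trajectory(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=np.asarray(traj.times))
        snaps = f.create_group("snapshots")
        masks = f.create_group("masks")
        for i, (fields, mk) in enumerate(zip(traj.snapshots, traj.masks)):
            g = snaps.create_group(str(i))
            for name, arr in fields.items():
                g.create_dataset(name, data=arr, compression="gzip", compression_opts=4)
            gm = masks.create_group(str(i))
            gm.create_dataset("omega", data=mk.omega.astype(np.uint8))
            gm.create_dataset("committed", data=mk.committed.astype(np.uint8))
            gm.create_dataset("crescent", data=mk.crescent.astype(np.uint8))
            gm.attrs["length"] = mk.length
        for key, val in traj.meta.items():
            f.attrs[key] = json.dumps(val) if isinstance(val, (dict, list)) else val
        from . import __version__

        f.attrs["version"] = __version__
    return path


def load_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    traj = Trajectory()
    with h5py.File(path, "r") as f:
        times = list(f["times"][...])
        meta = {}
        for key, val in f.attrs.items():
            if isinstance(val, str) and val[:1] in "{[":
                try:
                    val = json.loads(val)
                except json.JSONDecodeError:
                    pass
            meta[key] = val
        traj.meta = meta
        for i, t in enumerate(times):
            g = f[f"snapshots/{i}"]
            fields = {name: g[name][...] for name in g}
            gm = f[f"masks/{i}"]
            mk = DomainMasks(
                omega=gm["omega"][...].astype(bool),
                committed=gm["committed"][...].astype(bool),
                crescent=gm["crescent"][...].astype(bool),
                length=float(gm.attrs.get("length", 0.0)),
            )
            traj.append(float(t), fields, mk)
    return traj


def save_metrics_json(metrics: dict | list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(metrics, indent=2, default=_jsonable))
    return path


def save_metrics_csv(rows: list[dict], path: str | Path) -> Path:
    """One row per snapshot, fixed column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not rows:
        path.write_text("")
        return path
    cols = list(rows[0].keys())
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for r in rows:
            writer.writerow({k: _jsonable(r.get(k)) for k in cols})
    return path


def save_mask_csv(mask: np.ndarray, path: str | Path) -> Path:
    """Binary 0/1 matrix, one grid row per line, for eyeball inspection."""
    path = Path(path)
    np.savetxt(path, mask.astype(int), fmt="%d", delimiter=",")
    return path


def _jsonable(x):
    if isinstance(x, np.generic):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x
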