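"""Quick-look PNG rendering of trajectory snapshots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .solver import Trajectory

_CMAPS = {"A": "viridis", "S": "cividis", "B": "magma", "I": "inferno",
          "dot_field": "RdBu_r", "stripe_field": "RdBu_r"}


def render_snapshot(traj: Trajectory, index: int, path: str | Path) -> Path:
    """Render every field of one snapshot, masked to the digit, to a PNG."""
    fields = traj.snapshots[index]
    mk = traj.masks[index]
    n = len(fields)
    fig, axes = plt.subplots(n, 1, figsize=(10, 2.2 * n), squeeze=False)
    for ax, (name, arr) in zip(axes[:, 0], sorted(fields.items())):
        shown = np.where(mk.omega, arr, np.nan) if not mk.omega.all() else arr
        im = ax.imshow(shown, cmap=_CMAPS.get(name, "viridis"), origin="lower")
        ax.set_title(f"{name}  (t = {traj.times[index]:g})")
        ax.set_xticks([]), ax.set_yticks([])
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def render_timecourse(traj: Trajectory, field: str, path: str | Path) -> Path:
    """One panel per snapshot of a single field — the growth storyboard."""
    n = len(traj.times)
    fig, axes = plt.subplots(n, 1, figsize=(10, 1.6 * n), squeeze=False)
    for ax, t, snap, mk in zip(axes[:, 0], traj.times, traj.snapshots, traj.masks):
        arr = snap[field]
        shown = np.where(mk.omega, arr, np.nan) if not mk.omega.all() else arr
        ax.imshow(shown, cmap=_CMAPS.get(field, "viridis"), origin="lower")
        ax.set_title(f"t = {t:g}", fontsize=8)
        ax.set_xticks([]), ax.set_yticks([])
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
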