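"""Digit-shaped simulation domains on a regular grid.

The digit is modelled as a rectangle of length ``L`` and width ``W`` capped
on both ends by half-ellipses of along-axis extent ``eps`` (the caps are
appended, so the total extent is ``L + 2*eps``).  The digit lies along the
+x axis of a larger rectangular grid of square bins; a binary mask ``omega``
marks bins whose *centre* falls inside the continuous shape.  Growth is
purely along the digit axis: the rectangle length increases linearly in time
from ``L0`` to ``L`` while the proximal end stays anchored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised when a digit shape does not fit its grid."""


@dataclass(frozen=True)
class GridSpec:
    """A regular grid of square bins, ``nx`` columns by ``ny`` rows."""

    nx: int
    ny: int
    h: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError(f"grid must be at least 8x8 bins, got {self.nx}x{self.ny}")
        if self.h <= 0:
            raise ValueError(f"bin size h must be positive, got {self.h}")

    @property
    def shape(self) -> tuple[int, int]:
        # array convention: [row=y, col=x]
        return (self.ny, self.nx)

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.h

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.h

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Bin-centre coordinates as (X, Y) arrays of shape (ny, nx)."""
        return np.meshgrid(self.x_centers, self.y_centers)


@dataclass(frozen=True)
class DigitGeometry:
    """Stadium-shaped digit: rectangle ``L x W`` plus half-ellipse caps.

    ``anchor`` is the (x, y) coordinate of the proximal rectangle end on the
    digit midline; the digit extends toward +x.
    """

    L0: float
    L: float
    W: float
    eps: float = 0.0
    anchor: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0 < self.L0 <= self.L):
            raise ValueError(f"need 0 < L0 <= L, got L0={self.L0}, L={self.L}")
        if self.W <= 0:
            raise ValueError(f"width must be positive, got {self.W}")
        if self.eps < 0:
            raise ValueError(f"cap length eps must be >= 0, got {self.eps}")


@dataclass(frozen=True)
class GrowthSchedule:
    """Time course of the digit rectangle length.

    mode:
        ``static``          -- length fixed at ``L`` for the whole run.
        ``tip``             -- distal tip advances; length L0 -> L linearly
                               between the settling time ``T_i`` and ``T``.
        ``tip_and_stretch`` -- length increments are split between uniform
                               stretching (fraction ``stretch_ratio``) and
                               distal tip extension.
    """

    mode: str = "static"
    T: float = 100.0
    T_i: float = 0.0
    stretch_ratio: float = 0.0

    _MODES = ("static", "tip", "tip_and_stretch")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}, got {self.mode!r}")
        if not (0 <= self.T_i < self.T):
            raise ValueError(f"need 0 <= T_i < T, got T_i={self.T_i}, T={self.T}")
        if not (0.0 <= self.stretch_ratio <= 1.0):
            raise ValueError(f"stretch_ratio must be in [0,1], got {self.stretch_ratio}")

    def length_at(self, t: float, geom: DigitGeometry) -> float:
        """Rectangle length at time ``t`` (non-decreasing, piecewise linear)."""
        if self.mode == "static":
            return geom.L
        if t <= self.T_i:
            return geom.L0
        frac = min(1.0, (t - self.T_i) / (self.T - self.T_i))
        return geom.L0 + frac * (geom.L - geom.L0)


@dataclass(frozen=True)
class DomainMasks:
    """Binary masks defining the digit domain and its special regions.

    ``omega`` is 1 inside the digit; ``committed`` marks proximal bins whose
    state is frozen; ``crescent`` marks the distal boundary strip with extra
    source terms.  ``length`` records the rectangle length the masks were
    built for.
    """

    omega: np.ndarray
    committed: np.ndarray
    crescent: np.ndarray
    length: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega", "committed", "crescent"):
            arr = getattr(self, name)
            if arr.dtype != bool:
                object.__setattr__(self, name, arr.astype(bool))

    @property
    def active(self) -> np.ndarray:
        """Inside bins that are not frozen."""
        return self.omega & ~self.committed


def empty_masks(grid: GridSpec) -> DomainMasks:
    """All-outside masks (plain-rectangle runs use omega = everything instead)."""
    z = np.zeros(grid.shape, dtype=bool)
    return DomainMasks(z, z.copy(), z.copy(), 0.0)


def full_masks(grid: GridSpec) -> DomainMasks:
    """Masks for an unmasked rectangular domain (the whole grid is inside)."""
    o = np.ones(grid.shape, dtype=bool)
    z = np.zeros(grid.shape, dtype=bool)
    return DomainMasks(o, z, z.copy(), grid.nx * grid.h)


def _check_fit(geom: DigitGeometry, grid: GridSpec, length: float) -> None:
    x0, yc = geom.anchor
    margin = 2 * grid.h
    lims = {
        "proximal (x low)": (x0 - geom.eps) - margin,
        "distal (x high)": (grid.nx * grid.h - margin) - (x0 + length + geom.eps),
        "lateral (y low)": (yc - geom.W / 2) - margin,
        "lateral (y high)": (grid.ny * grid.h - margin) - (yc + geom.W / 2),
    }
    for name, slack in lims.items():
        if slack < -1e-9:
            raise GeometryError(
                f"digit exceeds the {name} grid margin by {-slack:.3g} "
                f"(a 2-bin margin is required)"
            )


def build_digit_mask(
    geom: DigitGeometry, grid: GridSpec, current_length: float
) -> DomainMasks:
    """Binary digit mask at a given rectangle length (bin-centre inside test)."""
    if not (geom.L0 - 1e-9 <= current_length <= geom.L + 1e-9):
        raise ValueError(
            f"current_length {current_length} outside [L0, L] = [{geom.L0}, {geom.L}]"
        )
    _check_fit(geom, grid, current_length)
    X, Y = grid.meshgrid()
    x0, yc = geom.anchor
    x1 = x0 + current_length
    half_w = geom.W / 2
    inside = (X >= x0) & (X <= x1) & (np.abs(Y - yc) <= half_w)
    if geom.eps > 0:
        # half-ellipse caps appended beyond both rectangle ends; evaluate the
        # ellipse only within the cap's bounding strip to avoid overflow for
        # tiny eps
        ell_y = ((Y - yc) / half_w) ** 2
        for strip, dx in (
            ((X > x1) & (X <= x1 + geom.eps), X - x1),
            ((X < x0) & (X >= x0 - geom.eps), x0 - X),
        ):
            frac = np.divide(dx, geom.eps, out=np.full_like(X, np.inf), where=strip)
            inside |= strip & (frac**2 + ell_y <= 1.0)
    z = np.zeros(grid.shape, dtype=bool)
    return DomainMasks(inside, z, z.copy(), current_length)


def advance_geometry(
    masks: DomainMasks | None,
    geom: DigitGeometry,
    sched: GrowthSchedule,
    t: float,
    grid: GridSpec,
) -> DomainMasks:
    """Digit mask at time ``t``; tip growth advances the distal cap only.

    The new length is rounded to bin resolution so the mask only changes at
    whole-bin increments.
    """
    if t < -1e-9 or t > sched.T + 1e-9:
        raise ValueError(f"t={t} outside the schedule interval [0, {sched.T}]")
    length = sched.length_at(t, geom)
    length = np.clip(round(length / grid.h) * grid.h, geom.L0, geom.L)
    return build_digit_mask(geom, grid, float(length))


def build_committed_mask(
    masks: DomainMasks, geom: DigitGeometry, L_P: float, grid: GridSpec
) -> DomainMasks:
    """Freeze bins further than ``L_P`` (along the axis) from the distal tip.

    The distance is measured from the distal-most occupied bin column, with
    strict inequality, so ``L_P = 0`` commits everything except the tip
    column itself.
    """
    if L_P < 0:
        raise ValueError(f"L_P must be >= 0, got {L_P}")
    X, _ = grid.meshgrid()
    if not masks.omega.any():
        return replace(masks, committed=np.zeros(grid.shape, dtype=bool))
    x_tip = X[masks.omega].max()
    committed = masks.omega & ((x_tip - X) > L_P + 1e-9)
    return replace(masks, committed=committed)


def build_crescent_mask(
    masks: DomainMasks, geom: DigitGeometry, thickness: float, grid: GridSpec
) -> DomainMasks:
    """Distal boundary strip: inside bins within ``thickness`` of the distal cap.

    Models the digital crescent / phalanx-forming region at the growing tip.
    """
    if thickness <= 0:
        return replace(masks, crescent=np.zeros(grid.shape, dtype=bool))
    if thickness >= geom.W / 2:
        raise ValueError(f"crescent thickness {thickness} must be < W/2 = {geom.W / 2}")
    X, _ = grid.meshgrid()
    x0 = geom.anchor[0]
    x_end = x0 + masks.length
    outside_distal = ~masks.omega & (X >= x_end)
    if not outside_distal.any():
        return replace(masks, crescent=np.zeros(grid.shape, dtype=bool))
    # distance (in bins) from each bin to the nearest distal-outside bin
    dist = ndimage.distance_transform_edt(~outside_distal) * grid.h
    crescent = masks.omega & (dist <= thickness + 1e-9)
    return replace(masks, crescent=crescent)


def stretch_uniform(
    state_fields: dict[str, np.ndarray],
    masks: DomainMasks,
    geom: DigitGeometry,
    factor: float,
    grid: GridSpec,
) -> tuple[dict[str, np.ndarray], DomainMasks]:
    """Uniform along-axis growth: resample fields about the proximal anchor.

    Every field is linearly interpolated so that material at distance ``d``
    from the anchor moves to ``factor * d``; the mask is rebuilt at the
    stretched length.  Bins outside both the old and new digit keep their
    values.
    """
    if factor < 1.0:
        raise ValueError(f"stretch factor must be >= 1, got {factor}")
    new_length = masks.length * factor
    if new_length > geom.L + 1e-9:
        new_length = geom.L
        factor = new_length / masks.length
    if factor == 1.0:
        return {k: v.copy() for k, v in state_fields.items()}, masks
    _check_fit(geom, grid, new_length)

    x0 = geom.anchor[0]
    x = grid.x_centers
    # source x-coordinate that lands on each bin centre after stretching
    x_src = np.where(x >= x0, x0 + (x - x0) / factor, x)
    ix_src = np.clip(x_src / grid.h - 0.5, 0, grid.nx - 1)
    iy = np.arange(grid.ny)
    cols, rows = np.meshgrid(ix_src, iy)
    coords = np.stack([rows, cols])

    new_masks = build_digit_mask(geom, grid, new_length)
    new_masks = replace(new_masks, committed=masks.committed, crescent=masks.crescent)
    out_fields: dict[str, np.ndarray] = {}
    for name, f in state_fields.items():
        stretched = ndimage.map_coordinates(f, coords, order=1, mode="nearest")
        out = f.copy()
        sel = new_masks.omega
        out[sel] = stretched[sel]
        out_fields[name] = out
    return out_fields, new_masks
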