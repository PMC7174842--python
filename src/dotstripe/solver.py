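"""Operator-splitting solver on the masked, growing domain.

Each time step applies, in order:

1. an implicit (backward-Euler) linear step per species, computed in the
   type-2 discrete cosine basis so reflective (zero-flux) boundaries at the
   grid edge are exact — plain diffusion for the four-species model, the
   biharmonic Swift-Hohenberg operator for the generic model;
2. a forward-Euler reaction step using the mask-dependent local rates;
3. optional clipping of negative concentrations;
4. re-freezing of committed bins (they diffuse into neighbours but never
   change themselves);
5. every ``growth_every`` steps, a geometry update: the digit mask advances
   (tip growth), optionally preceded by a uniform stretch of the state;
   newly inside bins simply keep their prior (outside) values.

The scheme is first-order in time; the linear step is unconditionally
stable and exact for the discrete operator, so ``dt`` is limited only by
the explicit reaction step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Protocol

import numpy as np
from scipy.fft import dctn, idctn

from .geometry import (
    DigitGeometry,
    DomainMasks,
    GridSpec,
    GrowthSchedule,
    advance_geometry,
    build_committed_mask,
    build_crescent_mask,
    full_masks,
    stretch_uniform,
)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    """Time stepping, initialization and output cadence."""

    dt: float = 0.05
    T: float = 150.0
    T_i: float = 0.0
    seed: int = 0
    noise_amp: float = 0.01
    noise_dist: str = "uniform"
    snapshot_every: int = 500
    growth_every: int = 20
    clip_negative: bool = True
    overflow_guard: float = 1e6

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.snapshot_every < 1 or self.growth_every < 1:
            raise ValueError("snapshot_every and growth_every must be >= 1")
        if self.noise_dist not in ("uniform", "gaussian"):
            raise ValueError(f"unknown noise_dist {self.noise_dist!r}")


@dataclass
class Trajectory:
    """Ordered snapshots of a run plus the metadata needed to reproduce it."""

    times: list[float] = field(default_factory=list)
    snapshots: list[dict[str, np.ndarray]] = field(default_factory=list)
    masks: list[DomainMasks] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def append(self, t: float, fields: dict[str, np.ndarray], masks: DomainMasks) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("snapshot times must be strictly increasing")
        self.times.append(t)
        self.snapshots.append({k: v.copy() for k, v in fields.items()})
        self.masks.append(masks)

    @property
    def final_fields(self) -> dict[str, np.ndarray]:
        return self.snapshots[-1]

    @property
    def final_masks(self) -> DomainMasks:
        return self.masks[-1]


class Model(Protocol):
    """What the solver needs from a model (four-species or Swift-Hohenberg)."""

    species: tuple[str, ...]
    clip_negative: bool
    frozen: dict[str, np.ndarray | float]

    def initial_values(self) -> dict[str, float]: ...

    def linear_symbol(self, name: str, lam: np.ndarray, dt: float) -> np.ndarray:
        """Denominator of the implicit step in the cosine basis."""
        ...

    def local_rates(
        self, fields: dict[str, np.ndarray], masks: DomainMasks
    ) -> dict[str, np.ndarray]: ...


# ---------------------------------------------------------------------------
# spectral building blocks


def neumann_laplacian_eigenvalues(grid: GridSpec) -> np.ndarray:
    """Eigenvalues of minus the discrete Neumann Laplacian in the DCT-II basis.

    Per axis, mode m of n has eigenvalue (2/h^2) (1 - cos(pi m / n)); the 2-D
    value is the sum over axes (shape (ny, nx)).
    """
    lam_x = (2.0 / grid.h**2) * (1.0 - np.cos(np.pi * np.arange(grid.nx) / grid.nx))
    lam_y = (2.0 / grid.h**2) * (1.0 - np.cos(np.pi * np.arange(grid.ny) / grid.ny))
    return lam_y[:, None] + lam_x[None, :]


def _dct2(f: np.ndarray) -> np.ndarray:
    return dctn(f, type=2, norm="ortho")


def _idct2(F: np.ndarray) -> np.ndarray:
    return idctn(F, type=2, norm="ortho")


def implicit_diffusion_step(
    field_arr: np.ndarray, D: float, dt: float, grid: GridSpec
) -> np.ndarray:
    """Backward-Euler diffusion step, exact for the discrete operator.

    Solves (1 - dt D lap) u_new = u_old with reflective boundaries; the
    k=0 mode is untouched, so the field total is conserved exactly.
    """
    if D == 0:
        return field_arr.copy()
    lam = neumann_laplacian_eigenvalues(grid)
    return _idct2(_dct2(field_arr) / (1.0 + dt * D * lam))


def implicit_sh_linear_step(
    field_arr: np.ndarray, ell: float, dt: float, grid: GridSpec
) -> np.ndarray:
    """Backward-Euler step for the Swift-Hohenberg operator -(1 + ell^2 lap)^2.

    Solves (1 + dt (1 - ell^2 lam)^2) u_new = u_old in the cosine basis; the
    symbol vanishes at the band centre k = 1/ell and equals 1 at k = 0 (a
    uniform field decays by 1/(1+dt)).
    """
    lam = neumann_laplacian_eigenvalues(grid)
    symbol = 1.0 + dt * (1.0 - ell**2 * lam) ** 2
    return _idct2(_dct2(field_arr) / symbol)


def explicit_reaction_step(
    fields: dict[str, np.ndarray],
    rates_fn: Callable[[dict[str, np.ndarray]], dict[str, np.ndarray]],
    dt: float,
    clip_negative: bool = False,
    step_index: int | None = None,
) -> dict[str, np.ndarray]:
    """Forward-Euler reaction update ``field += dt * rate``."""
    rates = rates_fn(fields)
    out: dict[str, np.ndarray] = {}
    for name, f in fields.items():
        r = rates.get(name)
        g = f if r is None else f + dt * r
        if np.isnan(g).any():
            where = f" at step {step_index}" if step_index is not None else ""
            raise SimulationError(f"NaN produced in field {name}{where}")
        if clip_negative:
            g = np.maximum(g, 0.0)
        out[name] = g
    return out


# ---------------------------------------------------------------------------
# initialization and the main loop


def initialize_state(
    model: Model, masks: DomainMasks, config: SolverConfig, grid: GridSpec
) -> dict[str, np.ndarray]:
    """Uniform base state (homogeneous steady state, or zero for SH) plus
    seeded stochastic noise; frozen species take their prescribed values
    exactly."""
    rng = np.random.default_rng(config.seed)
    base = model.initial_values()
    fields: dict[str, np.ndarray] = {}
    for name in model.species:
        if name in model.frozen:
            fields[name] = np.broadcast_to(
                np.asarray(model.frozen[name], float), grid.shape
            ).copy()
            continue
        if config.noise_dist == "uniform":
            noise = rng.uniform(-config.noise_amp, config.noise_amp, grid.shape)
        else:
            noise = rng.normal(0.0, config.noise_amp, grid.shape)
        arr = np.full(grid.shape, base[name], dtype=float) + noise
        if model.clip_negative:
            arr = np.maximum(arr, 0.0)
        fields[name] = arr
    return fields


def _rebuild_special_masks(
    masks: DomainMasks,
    geom: DigitGeometry | None,
    grid: GridSpec,
    L_P: float | None,
    crescent_thickness: float | None,
) -> DomainMasks:
    if geom is None:
        return masks
    if L_P is not None:
        masks = build_committed_mask(masks, geom, L_P, grid)
    if crescent_thickness is not None:
        masks = build_crescent_mask(masks, geom, crescent_thickness, grid)
    return masks


def simulate(
    model: Model,
    grid: GridSpec,
    config: SolverConfig,
    geom: DigitGeometry | None = None,
    sched: GrowthSchedule | None = None,
    L_P: float | None = None,
    crescent_thickness: float | None = None,
    meta: dict | None = None,
) -> Trajectory:
    """Run a full simulation and return its snapshot trajectory.

    With ``geom=None`` the whole grid is inside the domain (plain
    rectangle).  Committed bins are stored the moment they enter the
    committed zone and reset to the stored values after every step.
    """
    if geom is not None and sched is None:
        sched = GrowthSchedule(mode="static", T=config.T)
    if sched is not None and sched.mode != "static" and sched.T > config.T + 1e-9:
        raise ValueError(
            "growth schedule must finish by the solver end time "
            f"(sched.T={sched.T} > T={config.T})"
        )

    if geom is None:
        masks = full_masks(grid)
    else:
        masks = advance_geometry(None, geom, sched, 0.0, grid)
    # the committed zone only starts freezing after the settling time T_i,
    # once the initial pattern has had a chance to form
    settle = sched.T_i if sched is not None else config.T_i
    masks = _rebuild_special_masks(
        masks, geom, grid, L_P if settle <= 0 else None, crescent_thickness
    )

    fields = initialize_state(model, masks, config, grid)
    store = {k: v.copy() for k, v in fields.items()}  # values of committed bins
    lam = neumann_laplacian_eigenvalues(grid)
    scale0 = max(1.0, max(float(np.abs(v).max()) for v in fields.values()))
    guard = config.overflow_guard * scale0

    traj = Trajectory(meta=dict(meta or {}, seed=config.seed))
    traj.append(0.0, fields, masks)

    n_steps = int(round(config.T / config.dt))
    growing = sched is not None and sched.mode != "static"

    def rates_fn(fl: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        return model.local_rates(fl, masks)

    for step in range(1, n_steps + 1):
        t = step * config.dt
        # 1) implicit linear step, per species
        for name in model.species:
            if name in model.frozen:
                continue
            denom = model.linear_symbol(name, lam, config.dt)
            if denom is not None:
                fields[name] = _idct2(_dct2(fields[name]) / denom)
                if model.clip_negative:
                    # backward-Euler diffusion preserves positivity up to
                    # spectral round-off; remove the resulting ~1e-16 dust
                    np.maximum(fields[name], 0.0, out=fields[name])
        # 2) explicit reactions (+ 3, clipping)
        fields = explicit_reaction_step(
            fields, rates_fn, config.dt, model.clip_negative, step
        )
        for name, val in model.frozen.items():
            fields[name] = np.broadcast_to(np.asarray(val, float), grid.shape).copy()
        # 4) committed bins never change
        if masks.committed.any():
            frozen_sel = masks.committed
            for name in model.species:
                fields[name][frozen_sel] = store[name][frozen_sel]
        if L_P is not None:
            # track the freeze store: committed bins keep their stored value,
            # active bins follow the state so newly committed bins freeze at
            # their current value
            for name in model.species:
                store[name] = np.where(masks.committed, store[name], fields[name])

        mx = max(float(np.abs(v).max()) for v in fields.values())
        if not np.isfinite(mx) or mx > guard:
            raise SimulationError(
                f"field overflow (|field| > {guard:.3g}) at step {step}, t={t:.3g}; "
                f"reduce dt (currently {config.dt})"
            )

        # commitment switches on at the end of the settling period
        if (
            L_P is not None
            and settle > 0
            and t > settle
            and (t - config.dt) <= settle
            and geom is not None
        ):
            masks = _rebuild_special_masks(masks, geom, grid, L_P, crescent_thickness)

        # 5) geometry update
        if growing and step % config.growth_every == 0 and t > sched.T_i:
            target = sched.length_at(t, geom)
            target = float(np.clip(round(target / grid.h) * grid.h, geom.L0, geom.L))
            if target > masks.length + 1e-9:
                if sched.mode == "tip_and_stretch" and sched.stretch_ratio > 0:
                    dL = target - masks.length
                    factor = (masks.length + sched.stretch_ratio * dL) / masks.length
                    # the freeze store is material too: transport it with the
                    # same resampling so committed values move with the tissue
                    store, _ = stretch_uniform(store, masks, geom, factor, grid)
                    fields, masks = stretch_uniform(fields, masks, geom, factor, grid)
                new_masks = replace(
                    advance_geometry(masks, geom, sched, t, grid),
                    committed=masks.committed,
                    crescent=masks.crescent,
                )
                masks = _rebuild_special_masks(
                    new_masks, geom, grid, L_P, crescent_thickness
                )

        if step % config.snapshot_every == 0 or step == n_steps:
            traj.append(t, fields, masks)

    return traj
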