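"""Run configuration: validated, serializable description of a simulation.

A :class:`RunConfig` collects every knob of a run — model choice and
parameters, grid, digit geometry, growth schedule, solver settings and
analysis constants — and is what the CLI, the preset catalogue and the
HDF5 metadata all speak.  Validation is strict: unknown keys are rejected
so a typo in a config file fails loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .geometry import DigitGeometry, GridSpec, GrowthSchedule
from .kinetics import CouplingParams, DotParams, StripeParams
from .models import FourSpeciesModel, SHModel
from .solver import SolverConfig
from .swifthohenberg import SHDotParams, SHStripeParams


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSection(_Section):
    nx: int = Field(144, ge=8)
    ny: int = Field(48, ge=8)
    h: float = Field(1.0, gt=0)

    def build(self) -> GridSpec:
        return GridSpec(self.nx, self.ny, self.h)


class GeometrySection(_Section):
    L0: float = 90.0
    L: float = 90.0
    W: float = 10.0
    eps: float = 5.0
    anchor_x: float = 24.0
    anchor_y: float = 24.0

    def build(self) -> DigitGeometry:
        return DigitGeometry(
            L0=self.L0, L=self.L, W=self.W, eps=self.eps,
            anchor=(self.anchor_x, self.anchor_y),
        )


class ScheduleSection(_Section):
    mode: Literal["static", "tip", "tip_and_stretch"] = "static"
    T: float = 150.0
    T_i: float = 0.0
    stretch_ratio: float = 0.0

    def build(self) -> GrowthSchedule:
        return GrowthSchedule(
            mode=self.mode, T=self.T, T_i=self.T_i, stretch_ratio=self.stretch_ratio
        )


class DotSection(_Section):
    k_A: float = 1.0
    mu_A: float = 1.0
    k_S: float = 1.0
    h_A: float = 0.1
    h_S: float = 1.0
    D_A: float = 2.5
    D_S: float = 50.0

    def build(self) -> DotParams:
        return DotParams(**self.model_dump())


class StripeSection(_Section):
    k_B: float = 2.0
    kappa_B: float = 0.15
    mu_B: float = 2.0
    k_I: float = 2.0
    mu_I: float = 2.0
    D_B: float = 1.2
    D_I: float = 54.0
    I_floor: float = 1e-6

    def build(self) -> StripeParams:
        return StripeParams(**self.model_dump())


class CouplingSection(_Section):
    variant: Literal["full", "stripe_only", "dot_hole"] = "full"
    s_act: float = 0.2
    s_thr: float = 6.0
    k_deg: float = 0.2
    h_A_DC: float = 0.0
    h_B_DC: float = 0.0
    outside_decay_BI: bool = False

    def build(self) -> CouplingParams:
        return CouplingParams(**self.model_dump())


class SHSection(_Section):
    alpha_dot: float = 0.2
    ell_dot: float = 3.2
    gamma: float = 1.2
    k_deg_sh: float = 0.5
    alpha0: float = 0.3
    ell_stripe: float = 2.0
    h0: float = 0.3
    tau: float = 1.0
    s_alpha: float = 0.8
    s_h: float = 0.8
    coupling_mode: Literal["none", "h_only", "alpha_only", "both"] = "both"

    def build(self) -> tuple[SHDotParams, SHStripeParams]:
        return (
            SHDotParams(
                alpha_dot=self.alpha_dot, ell_dot=self.ell_dot,
                gamma=self.gamma, k_deg_sh=self.k_deg_sh,
            ),
            SHStripeParams(
                alpha0=self.alpha0, ell_stripe=self.ell_stripe, h0=self.h0,
                tau=self.tau, s_alpha=self.s_alpha, s_h=self.s_h,
            ),
        )


class SolverSection(_Section):
    dt: float = Field(0.05, gt=0)
    T: float = Field(150.0, gt=0)
    T_i: float = Field(0.0, ge=0)
    seed: int = 0
    noise_amp: float = Field(0.02, ge=0)
    noise_dist: Literal["uniform", "gaussian"] = "uniform"
    snapshot_every: int = Field(3000, ge=1)
    growth_every: int = Field(20, ge=1)
    clip_negative: bool = True
    overflow_guard: float = 1e6

    def build(self) -> SolverConfig:
        return SolverConfig(**self.model_dump())


class RunConfig(_Section):
    """Top-level, fully resolved run description."""

    model: Literal["dotstripe", "sh", "stripe_only", "dot_hole"] = "dotstripe"
    preset: Optional[str] = None
    seed: int = 0
    use_digit: bool = True
    L_P: Optional[float] = None
    crescent_thickness: Optional[float] = None
    joint_marker: Optional[str] = None
    grid: GridSection = GridSection()
    geometry: GeometrySection = GeometrySection()
    schedule: ScheduleSection = ScheduleSection()
    dot: DotSection = DotSection()
    stripe: StripeSection = StripeSection()
    coupling: CouplingSection = CouplingSection()
    sh: SHSection = SHSection()
    solver: SolverSection = SolverSection()

    @model_validator(mode="after")
    def _sync(self) -> "RunConfig":
        # the model key selects the four-species variant
        if self.model == "stripe_only" and self.coupling.variant != "stripe_only":
            self.coupling = self.coupling.model_copy(update={"variant": "stripe_only"})
        if self.model == "dot_hole" and self.coupling.variant != "dot_hole":
            self.coupling = self.coupling.model_copy(update={"variant": "dot_hole"})
        if self.solver.seed != self.seed:
            self.solver = self.solver.model_copy(update={"seed": self.seed})
        return self

    # ------------------------------------------------------------------
    def build_model(self) -> FourSpeciesModel | SHModel:
        if self.model == "sh":
            dotp, stripep = self.sh.build()
            m = SHModel(dot=dotp, stripe=stripep, coupling_mode=self.sh.coupling_mode)
        else:
            m = FourSpeciesModel(
                dot=self.dot.build(),
                stripe=self.stripe.build(),
                coupling=self.coupling.build(),
            )
        if self.joint_marker:
            m.joint_marker = self.joint_marker
        return m

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def run(self):
        """Build everything and run the simulation; returns a Trajectory."""
        from .solver import simulate

        grid = self.grid.build()
        geom = self.geometry.build() if self.use_digit else None
        sched = self.schedule.build() if self.use_digit else None
        traj = simulate(
            self.build_model(), grid, self.solver.build(),
            geom=geom, sched=sched,
            L_P=self.L_P, crescent_thickness=self.crescent_thickness,
            meta={"config": self.model_dump(), "config_hash": self.config_hash()},
        )
        return traj


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    A config naming only a preset starts from that preset's values; any
    other keys in the file override it.  Resolution is deterministic and
    idempotent.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    if "preset" in data and data["preset"]:
        from .presets import preset

        base = preset(data["preset"]).model_dump()
        base = _deep_update(base, {k: v for k, v in data.items() if k != "preset"})
        base["preset"] = data["preset"]
        data = base
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # pydantic error message already names key+constraint
        raise ConfigError(str(exc)) from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg.model_dump(), indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def _deep_update(base: dict, upd: dict) -> dict:
    out = dict(base)
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out
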