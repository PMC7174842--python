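"""Preset experiment catalogue.

Each preset is a fully resolved :class:`~dotstripe.config.RunConfig`
reproducing one qualitative patterning regime: the wild-type digit
(midline dots with interspersed transverse joint stripes), sequential
joint addition under tip growth, the committed zone, uniform growth with
a proximal-to-distal phalanx-length gradient, misoriented joints at
reduced dot-system diffusivities, wide-domain joint lattices, the
stripe-only and dot-hole alternative models, the generic Swift-Hohenberg
runs, and the clamp experiments.

Parameter provenance: the defaults in :mod:`dotstripe.kinetics` and
:mod:`dotstripe.swifthohenberg` were fixed once by a dispersion-relation
scan (dot wavelength ~ 2x stripe wavelength ~ 2x digit width, stripe
subsystem stable at dot-centre conditions and unstable far from dots) and
are version-pinned here; presets only vary geometry, schedule, diffusivity
scale factors and boundary rates, mirroring the parameter-variation
protocol of the underlying study.
"""

from __future__ import annotations

from .config import RunConfig

_CAT: dict[str, dict] = {}


def _register(name: str, **kw) -> None:
    _CAT[name] = kw


def _digit(W: float, L: float, L0: float | None = None, nx: int = 144, ny: int = 48):
    return {
        "grid": {"nx": nx, "ny": ny},
        "geometry": {"W": W, "eps": W / 2, "L": L, "L0": L0 if L0 is not None else L},
    }


# --- four-species regimes --------------------------------------------------

_register(
    "fig1F_wildtype",
    model="dotstripe",
    **_digit(W=10, L=90),
    schedule={"mode": "static", "T": 150.0},
    solver={"T": 150.0, "snapshot_every": 3000},
)

_GROWTH = {
    "coupling": {"outside_decay_BI": True, "h_B_DC": 4.0},
    "crescent_thickness": 3.0,
}

_register(
    "fig2B_growth",
    model="dotstripe",
    **_digit(W=10, L=90, L0=30, nx=176),
    schedule={"mode": "tip", "T": 300.0, "T_i": 60.0},
    solver={"T": 330.0, "snapshot_every": 600, "growth_every": 20},
    **_GROWTH,
)

_register(
    "fig2C_committed",
    model="dotstripe",
    **_digit(W=10, L=90, L0=30, nx=176),
    schedule={"mode": "tip", "T": 400.0, "T_i": 60.0},
    solver={"T": 430.0, "snapshot_every": 2000, "growth_every": 20},
    L_P=40.0,  # study protocol also uses 25 and 60; override L_P to compare
    **_GROWTH,
)

_register(
    "fig2D_uniform_growth",
    model="dotstripe",
    **_digit(W=10, L=120, L0=30, nx=200),
    schedule={"mode": "tip_and_stretch", "T": 500.0, "T_i": 80.0, "stretch_ratio": 0.7},
    solver={"T": 600.0, "snapshot_every": 3000, "growth_every": 20},
    L_P=50.0,
    **_GROWTH,
)

_register(
    "fig3B_jaws",
    model="dotstripe",
    **_digit(W=14, L=90),
    schedule={"mode": "static", "T": 200.0},
    solver={"T": 200.0, "snapshot_every": 4000},
    # dot-system wavelength halved: magnitudes down 4x at fixed D_S/D_A ratio
    dot={"D_A": 2.5 * 0.25, "D_S": 50.0 * 0.25},
)

_register(
    "fig4_lattice",
    model="dotstripe",
    use_digit=False,
    grid={"nx": 192, "ny": 192},
    solver={"T": 150.0, "snapshot_every": 3000},
    # dot spacing widened 1.5x (fixed ratio) so the joint network closes
    dot={"D_A": 2.5 * 1.5, "D_S": 50.0 * 1.5},
)

_register(
    "fig5A_stripe_only",
    model="stripe_only",
    use_digit=False,
    grid={"nx": 192, "ny": 192},
    solver={"T": 150.0, "snapshot_every": 3000},
    joint_marker="I",
)

_register(
    "fig5B_dot_hole",
    model="dot_hole",
    **_digit(W=10, L=90),
    schedule={"mode": "static", "T": 150.0},
    solver={"T": 150.0, "snapshot_every": 3000},
    joint_marker="S",
)

# --- generic Swift-Hohenberg regimes --------------------------------------

_SH_SOLVER = {
    "T": 250.0,
    "snapshot_every": 5000,
    "noise_amp": 0.05,
    "clip_negative": False,
}

_register(
    "fig6B_sh_narrow",
    model="sh",
    **_digit(W=12, L=90),
    schedule={"mode": "static", "T": 250.0},
    solver=dict(_SH_SOLVER),
    sh={"coupling_mode": "both"},
)

_register(
    "fig6B_sh_wide",
    model="sh",
    use_digit=False,
    grid={"nx": 144, "ny": 144},
    solver=dict(_SH_SOLVER),
    sh={"coupling_mode": "both"},
)

_register(
    "figS4_h_only",
    model="sh",
    use_digit=False,
    grid={"nx": 144, "ny": 144},
    solver=dict(_SH_SOLVER),
    sh={"coupling_mode": "h_only", "alpha0": 0.0},
)

_register(
    "figS4_alpha_only",
    model="sh",
    use_digit=False,
    grid={"nx": 144, "ny": 144},
    solver=dict(_SH_SOLVER),
    sh={"coupling_mode": "alpha_only", "h0": 0.0},
)

_register(
    "figS4_combined",
    model="sh",
    use_digit=False,
    grid={"nx": 144, "ny": 144},
    solver=dict(_SH_SOLVER),
    sh={"coupling_mode": "both"},
)

# --- growth-speed and crescent variants ------------------------------------

_register(
    "figS2A_fast_patterning",
    model="dotstripe",
    **_digit(W=10, L=90, L0=30, nx=176),
    # pattern equilibrates far faster than the digit grows
    schedule={"mode": "tip", "T": 600.0, "T_i": 60.0},
    solver={"T": 630.0, "snapshot_every": 1200, "growth_every": 20},
    **_GROWTH,
)

_register(
    "figS2B_crescent",
    model="dotstripe",
    **_digit(W=10, L=90, L0=30, nx=176),
    schedule={"mode": "tip", "T": 300.0, "T_i": 60.0},
    solver={"T": 330.0, "snapshot_every": 600, "growth_every": 20},
    coupling={"outside_decay_BI": True, "h_B_DC": 4.0, "h_A_DC": 0.3},
    crescent_thickness=3.0,
)

# --- clamp experiments (run through dotstripe.analysis helpers) -------------

_register(
    "figS3A_clamp",
    model="dotstripe",
    use_digit=False,
    grid={"nx": 96, "ny": 96},
    solver={"T": 100.0, "snapshot_every": 2000},
)

_register(
    "figS3B_gradient",
    model="dotstripe",
    use_digit=False,
    grid={"nx": 96, "ny": 96},
    solver={"T": 100.0, "snapshot_every": 2000},
)

# five (A, S) clamp values tracing dot centre -> far from dot, read off the
# wild-type pattern's extremes
CLAMP_PATH: tuple[tuple[float, float], ...] = (
    (3.0, 0.25),
    (2.3, 0.45),
    (1.6, 0.65),
    (0.9, 0.85),
    (0.2, 1.05),
)


def preset_names() -> list[str]:
    return sorted(_CAT)


def preset(name: str, seed: int = 0) -> RunConfig:
    """Resolved configuration for a named regime (unknown name lists all)."""
    if name not in _CAT:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        )
    cfg = RunConfig.model_validate({"preset": name, "seed": seed, **_CAT[name]})
    return cfg
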