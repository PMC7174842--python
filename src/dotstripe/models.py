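"""Model adapters binding reaction kinetics to the operator-splitting solver.

``FourSpeciesModel`` runs the molecular dot-stripe system (variants: full,
stripe_only, dot_hole); ``SHModel`` runs the generic Swift-Hohenberg
formulation.  Either exposes the same small surface the solver consumes:
species names, the implicit-step spectral symbol per species, the local
reaction rates, and initial values.

``frozen`` maps species names to prescribed constant fields (scalar or
array); frozen species are never stepped — this implements the clamp
experiments in which (A, S) are held at chosen values while (B, I) respond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DomainMasks
from .kinetics import (
    CouplingParams,
    DotParams,
    StripeParams,
    dot_rates,
    homogeneous_steady_state,
    stripe_rates,
)
from .swifthohenberg import (
    SHDotParams,
    SHStripeParams,
    sh_dot_rhs,
    sh_stripe_rhs,
)


@dataclass
class FourSpeciesModel:
    dot: DotParams = field(default_factory=DotParams)
    stripe: StripeParams = field(default_factory=StripeParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    frozen: dict[str, np.ndarray | float] = field(default_factory=dict)
    clip_negative: bool = True
    joint_marker: str = "B"

    def __post_init__(self) -> None:
        if self.coupling.variant == "stripe_only":
            self.species = ("B", "I")
            self.joint_marker = "I"
        elif self.coupling.variant == "dot_hole":
            self.species = ("A", "S")
            self.joint_marker = "S"
        else:
            self.species = ("A", "S", "B", "I")
        unknown = set(self.frozen) - set(self.species) - {"A", "S"}
        if unknown:
            raise ValueError(f"cannot freeze unknown species {sorted(unknown)}")
        # clamp runs freeze (A, S) even in a (B, I)-only simulation
        extra = tuple(s for s in ("A", "S") if s in self.frozen and s not in self.species)
        self.species = self.species + extra
        self._sstate = homogeneous_steady_state(self.dot, self.stripe, self.coupling)

    @property
    def steady_state(self) -> tuple[float, float, float, float]:
        """(A*, S*, B*, I*); the stripe pair is (0, 0) in the dot_hole variant."""
        return self._sstate

    def initial_values(self) -> dict[str, float]:
        A, S, B, I = self._sstate
        return {"A": A, "S": S, "B": B, "I": I}

    def linear_symbol(self, name: str, lam: np.ndarray, dt: float) -> np.ndarray:
        D = {
            "A": self.dot.D_A,
            "S": self.dot.D_S,
            "B": self.stripe.D_B,
            "I": self.stripe.D_I,
        }[name]
        return 1.0 + dt * D * lam

    def local_rates(
        self, fields: dict[str, np.ndarray], masks: DomainMasks
    ) -> dict[str, np.ndarray]:
        A_star, S_star, _, _ = self._sstate
        rates: dict[str, np.ndarray] = {}
        variant = self.coupling.variant
        if variant != "stripe_only":
            dA, dS = dot_rates(fields["A"], fields["S"], self.dot, self.coupling, masks)
            rates["A"], rates["S"] = dA, dS
        if variant != "dot_hole":
            if variant == "stripe_only":
                A = fields.get("A", np.zeros_like(fields["B"]))
                S = fields.get("S", np.zeros_like(fields["B"]))
            else:
                A, S = fields["A"], fields["S"]
            dB, dI = stripe_rates(
                fields["B"], fields["I"], A, S,
                self.stripe, self.coupling, masks,
                A_star=A_star or 1.0, S_star=S_star or 1.0,
            )
            rates["B"], rates["I"] = dB, dI
        for name in self.frozen:
            rates.pop(name, None)
        return rates


@dataclass
class SHModel:
    dot: SHDotParams = field(default_factory=SHDotParams)
    stripe: SHStripeParams = field(default_factory=SHStripeParams)
    coupling_mode: str = "both"
    frozen: dict[str, np.ndarray | float] = field(default_factory=dict)
    clip_negative: bool = False  # SH fields are sign-indefinite
    joint_marker: str = "stripe_field"
    species: tuple[str, ...] = ("dot_field", "stripe_field")

    def initial_values(self) -> dict[str, float]:
        return {"dot_field": 0.0, "stripe_field": 0.0}

    def linear_symbol(self, name: str, lam: np.ndarray, dt: float) -> np.ndarray:
        if name == "dot_field":
            return 1.0 + dt * (1.0 - self.dot.ell_dot**2 * lam) ** 2
        # the stripe equation runs on the rescaled time dt / tau
        dt_eff = dt / self.stripe.tau
        return 1.0 + dt_eff * (1.0 - self.stripe.ell_stripe**2 * lam) ** 2

    def local_rates(
        self, fields: dict[str, np.ndarray], masks: DomainMasks
    ) -> dict[str, np.ndarray]:
        u, v = fields["dot_field"], fields["stripe_field"]
        rates = {
            "dot_field": sh_dot_rhs(u, self.dot, masks),
            "stripe_field": sh_stripe_rhs(v, u, self.stripe, self.coupling_mode, masks)
            / self.stripe.tau,
        }
        for name in self.frozen:
            rates.pop(name, None)
        return rates
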