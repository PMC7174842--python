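"""Reaction kinetics of the four-species dot-stripe mechanism.

Two coupled Turing subsystems share one grid:

* **Dot subsystem** -- an activator-substrate pair.  The activator ``A``
  autocatalyses itself while consuming the substrate ``S`` (the classic
  A^2 S depletion nonlinearity), so ``A`` self-organizes into dots and
  ``S`` into the complementary holes:

      dA/dt = h_A + k_A * A^2 * S - mu_A * A        (inside the digit)
      dS/dt = h_S - k_S * A^2 * S

* **Stripe subsystem** -- a saturating activator-inhibitor pair.  ``B``
  self-activates (repressed by its fast-diffusing inhibitor ``I`` and
  self-limited at high ``B``), producing stripes:

      dB/dt = kb * B^2 / (I * (1 + kap * B^2)) - mu_B * B
      dI/dt = k_I * B^2 - mu_I * I

* **Coupling** -- the substrate activates stripe self-activation
  (``kb = k_B_eff(S)``, increasing in S) and the dot activator raises the
  stripe saturation threshold (``kap = kappa_eff(A)``, increasing in A), so
  stripes are favoured at maximal distance from dots and bisect them.

Outside the digit only ``A`` decays (rate ``k_deg``); in the digital
crescent at the growing tip, ``A`` gains a local source ``h_A_DC`` and
``B`` a local sink ``h_B_DC * B``.

Naming note: ``mu_A`` and ``mu_I`` are the linear degradation rates of A
and I (the literature sometimes reuses ``k_A``/``k_I`` for these, which
collides with the production-rate symbols used here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .geometry import DomainMasks

VARIANTS = ("full", "stripe_only", "dot_hole")


@dataclass(frozen=True)
class DotParams:
    """Activator-substrate (dot) subsystem parameters."""

    k_A: float = 1.0      # cross-activation of A by S (A^2 S autocatalysis)
    mu_A: float = 1.0     # linear degradation of A
    k_S: float = 1.0      # consumption of S by A
    h_A: float = 0.1      # constant production of A
    h_S: float = 1.0      # constant production of S
    D_A: float = 2.5      # activator diffusivity
    D_S: float = 50.0     # substrate diffusivity (must outrange D_A)

    def __post_init__(self) -> None:
        for name in ("k_A", "mu_A", "k_S", "h_A", "h_S", "D_A", "D_S"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.D_S <= self.D_A:
            raise ValueError(
                f"Turing instability requires D_S > D_A, got D_S={self.D_S}, D_A={self.D_A}"
            )


@dataclass(frozen=True)
class StripeParams:
    """Saturating activator-inhibitor (stripe) subsystem parameters."""

    k_B: float = 2.0        # self-activation of B
    kappa_B: float = 0.15   # saturation constant of self-activation
    mu_B: float = 2.0       # degradation of B
    k_I: float = 2.0        # activation of I by B
    mu_I: float = 2.0       # degradation of I
    D_B: float = 1.2        # activator diffusivity
    D_I: float = 54.0       # inhibitor diffusivity (must outrange D_B)
    I_floor: float = 1e-6   # regularizes the B^2/I division

    def __post_init__(self) -> None:
        for name in ("k_B", "kappa_B", "mu_B", "k_I", "mu_I", "D_B", "D_I"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.D_I <= self.D_B:
            raise ValueError(
                f"Turing instability requires D_I > D_B, got D_I={self.D_I}, D_B={self.D_B}"
            )
        if self.I_floor <= 0:
            raise ValueError("I_floor must be positive")


@dataclass(frozen=True)
class CouplingParams:
    """Dot-to-stripe coupling strengths, variant switch and boundary rates."""

    variant: str = "full"
    s_act: float = 0.2          # sensitivity of S -> B activation (exponent)
    s_thr: float = 6.0          # strength of A -> saturation-threshold increase
    k_deg: float = 0.2          # outside-digit degradation of A
    h_A_DC: float = 0.0         # crescent source of A
    h_B_DC: float = 0.0         # crescent sink rate of B
    outside_decay_BI: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        for name in ("s_act", "s_thr", "k_deg", "h_A_DC", "h_B_DC"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class Fields:
    """The four concentration fields on a common grid."""

    A: np.ndarray
    S: np.ndarray
    B: np.ndarray
    I: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"A": self.A, "S": self.S, "B": self.B, "I": self.I}


def _validate(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"field {name} contains non-finite values")
    if arr.min() < 0:
        raise ValueError(f"field {name} contains negative concentrations")


def dot_rates(
    A: np.ndarray,
    S: np.ndarray,
    p: DotParams,
    c: CouplingParams,
    masks: DomainMasks,
) -> tuple[np.ndarray, np.ndarray]:
    """Reaction rates (dA/dt, dS/dt); diffusion is handled by the solver.

    Inside the digit the full kinetics apply; outside, A decays at ``k_deg``
    and S is inert; crescent bins gain the extra source ``h_A_DC``.
    """
    _validate("A", A)
    _validate("S", S)
    inside = masks.omega
    auto = p.k_A * A * A * S
    dA = np.where(inside, p.h_A + auto - p.mu_A * A, -c.k_deg * A)
    dS = np.where(inside, p.h_S - p.k_S * A * A * S, 0.0)
    if masks.crescent.any() and c.h_A_DC:
        dA = dA + np.where(masks.crescent, c.h_A_DC, 0.0)
    return dA, dS


def k_B_eff(
    S: np.ndarray | float,
    c: CouplingParams,
    sp: StripeParams,
    S_star: float,
) -> np.ndarray | float:
    """Effective stripe self-activation rate, increasing in the substrate.

    ``k_B_eff = k_B * (S / S*)**s_act`` — strictly increasing in S, zero
    where the substrate is exhausted (dot centres), and equal to ``k_B`` at
    the homogeneous steady state.  The mild sensitivity (default
    ``s_act = 0.2``) keeps the stripe activator's autocatalytic drive from
    over-saturating where the substrate is abundant, so stripe
    self-organization switches on away from dots rather than at them.
    """
    if c.variant == "stripe_only":
        return sp.k_B if np.isscalar(S) else np.full_like(np.asarray(S, float), sp.k_B)
    if S_star <= 0:
        raise ValueError("substrate steady state S* must be positive for coupling")
    return sp.k_B * np.power(np.maximum(np.asarray(S, float), 0.0) / S_star, c.s_act)


def kappa_eff(
    A: np.ndarray | float,
    c: CouplingParams,
    sp: StripeParams,
    A_star: float,
) -> np.ndarray | float:
    """Effective stripe saturation constant, increasing in the dot activator."""
    if c.variant == "stripe_only":
        return (
            sp.kappa_B
            if np.isscalar(A)
            else np.full_like(np.asarray(A, float), sp.kappa_B)
        )
    if A_star <= 0:
        raise ValueError("activator steady state A* must be positive for coupling")
    return sp.kappa_B * (1.0 + c.s_thr * np.asarray(A, float) / A_star)


def stripe_rates(
    B: np.ndarray,
    I: np.ndarray,
    A: np.ndarray,
    S: np.ndarray,
    sp: StripeParams,
    c: CouplingParams,
    masks: DomainMasks,
    A_star: float = 1.0,
    S_star: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Reaction rates (dB/dt, dI/dt) of the coupled stripe subsystem."""
    _validate("B", B)
    _validate("I", I)
    inside = masks.omega
    kb = k_B_eff(S, c, sp, S_star)
    kap = kappa_eff(A, c, sp, A_star)
    B2 = B * B
    growth = kb * B2 / (np.maximum(I, sp.I_floor) * (1.0 + kap * B2))
    dB_in = growth - sp.mu_B * B
    dI_in = sp.k_I * B2 - sp.mu_I * I
    if c.outside_decay_BI:
        dB = np.where(inside, dB_in, -sp.mu_B * B)
        dI = np.where(inside, dI_in, -sp.mu_I * I)
    else:
        dB = np.where(inside, dB_in, 0.0)
        dI = np.where(inside, dI_in, 0.0)
    if masks.crescent.any() and c.h_B_DC:
        dB = dB - np.where(masks.crescent, c.h_B_DC * B, 0.0)
    return dB, dI


def homogeneous_steady_state(
    p: DotParams, sp: StripeParams, c: CouplingParams
) -> tuple[float, float, float, float]:
    """Positive homogeneous steady state (A*, S*, B*, I*).

    (A*, S*) is closed-form; (B*, I*) comes from the unique positive root of
    the cubic B (1 + kap * B^2) = k_B_eff * mu_I / (k_I * mu_B) evaluated at
    the coupled rates k_B_eff(S*), kappa_eff(A*).
    """
    if p.mu_A <= 0 or p.k_S <= 0:
        raise ValueError("dot subsystem needs mu_A > 0 and k_S > 0 for a steady state")
    A_star = (p.h_A + p.k_A * p.h_S / p.k_S) / p.mu_A
    if A_star <= 0:
        raise ValueError("dot subsystem admits no positive steady state")
    S_star = p.h_S / (p.k_S * A_star**2)

    if c.variant == "dot_hole":
        return A_star, S_star, 0.0, 0.0

    kb = sp.k_B if c.variant == "stripe_only" else float(k_B_eff(S_star, c, sp, S_star))
    kap = (
        sp.kappa_B
        if c.variant == "stripe_only"
        else float(kappa_eff(A_star, c, sp, A_star))
    )
    if sp.mu_B <= 0 or sp.k_I <= 0 or sp.mu_I <= 0 or kb <= 0:
        raise ValueError("stripe subsystem admits no positive steady state")
    target = kb * sp.mu_I / (sp.k_I * sp.mu_B)

    def g(B: float) -> float:
        return B * (1.0 + kap * B * B) - target

    hi = max(target, 1.0)
    while g(hi) < 0:
        hi *= 2.0
    B_star = brentq(g, 0.0, hi, xtol=1e-14, rtol=1e-14)
    I_star = sp.k_I * B_star**2 / sp.mu_I
    return A_star, S_star, float(B_star), float(I_star)


def dot_jacobian(p: DotParams) -> np.ndarray:
    """2x2 reaction Jacobian of the dot subsystem at its steady state."""
    A, S, _, _ = homogeneous_steady_state(p, StripeParams(), CouplingParams())
    return np.array(
        [
            [2 * p.k_A * A * S - p.mu_A, p.k_A * A * A],
            [-2 * p.k_S * A * S, -p.k_S * A * A],
        ]
    )


def turing_dispersion(J: np.ndarray, D: tuple[float, float], k: np.ndarray) -> np.ndarray:
    """Linear growth rate sigma(k): max Re eigenvalue of J - k^2 diag(D)."""
    k = np.atleast_1d(np.asarray(k, float))
    sig = np.empty_like(k)
    for i, ki in enumerate(k):
        M = J - ki**2 * np.diag(D)
        sig[i] = np.linalg.eigvals(M).real.max()
    return sig


def dot_linear_stability(
    p: DotParams, n_k: int = 4000
) -> tuple[float, float, float]:
    """Fastest-growing mode of the dot subsystem.

    Returns ``(k_max, lambda_pred, sigma_max)``: the wavenumber maximizing
    the dispersion relation, the predicted pattern wavelength 2*pi/k_max,
    and the peak growth rate (positive iff Turing-unstable).
    """
    J = dot_jacobian(p)
    # search out to several times the activator's kinetic wavenumber scale
    k_upper = 4.0 * np.sqrt(np.abs(J).max() / max(p.D_A, 1e-12))
    ks = np.linspace(1e-4, k_upper, n_k)
    sig = turing_dispersion(J, (p.D_A, p.D_S), ks)
    i = int(np.argmax(sig))
    sigma_max = float(sig[i])
    if sigma_max <= 0:
        # no finite-wavelength instability; report the (non-patterning) peak
        return float(ks[i]), float(2 * np.pi / ks[i]), sigma_max
    k_max = float(ks[i])
    return k_max, float(2 * np.pi / k_max), sigma_max


def stripe_jacobian(
    sp: StripeParams, kb: float, kap: float
) -> tuple[np.ndarray, float, float]:
    """Reaction Jacobian of the (B, I) subsystem at its positive steady state."""
    target = kb * sp.mu_I / (sp.k_I * sp.mu_B)

    def g(B: float) -> float:
        return B * (1.0 + kap * B * B) - target

    hi = max(target, 1.0)
    while g(hi) < 0:
        hi *= 2.0
    B = brentq(g, 0.0, hi, xtol=1e-14)
    I = sp.k_I * B**2 / sp.mu_I
    sat = kap * B * B
    f_B = sp.mu_B * (2.0 / (1.0 + sat) - 1.0)
    f_I = -sp.mu_B * B / I
    J = np.array([[f_B, f_I], [2 * sp.k_I * B, -sp.mu_I]])
    return J, float(B), float(I)


def stripe_linear_stability(
    sp: StripeParams, kb: float | None = None, kap: float | None = None, n_k: int = 4000
) -> tuple[float, float, float]:
    """Fastest-growing mode of the uncoupled (B, I) subsystem."""
    kb = sp.k_B if kb is None else kb
    kap = sp.kappa_B if kap is None else kap
    J, _, _ = stripe_jacobian(sp, kb, kap)
    k_upper = 4.0 * np.sqrt(np.abs(J).max() / max(sp.D_B, 1e-12))
    ks = np.linspace(1e-4, k_upper, n_k)
    sig = turing_dispersion(J, (sp.D_B, sp.D_I), ks)
    i = int(np.argmax(sig))
    sigma_max = float(sig[i])
    return float(ks[i]), float(2 * np.pi / ks[i]), sigma_max
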