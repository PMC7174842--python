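"""Generic one-field-per-subsystem dot-stripe model (Swift-Hohenberg form).

Any pattern-forming system near onset — molecular, cellular or mechanical —
reduces to the Swift-Hohenberg normal form, so a dot field ``u`` and a
stripe field ``v`` suffice to capture the dot-stripe logic independently of
mechanism:

    du/dt       = alpha_dot * u - (1 + ell_dot^2 lap)^2 u + gamma u^2 - u^3
    tau dv/dt   = alpha_eff(u) * v - (1 + ell_stripe^2 lap)^2 v - v^3 + h_eff(u)

``alpha_dot > 0`` guarantees dots form, ``ell_dot`` sets the dot spacing
(selected wavelength 2*pi*ell_dot), and the quadratic ``gamma`` term breaks
the up/down symmetry so the pattern is dots rather than stripes.  The
stripe equation carries an additive bias ``h`` promoting stripes and a
relative timescale ``tau``.

The coupling makes both the stripe instability parameter and the bias
decreasing functions of the rectified, normalized dot field:

    alpha_eff(u) = alpha0 - s_alpha * rect(u)
    h_eff(u)     = h0     - s_h     * rect(u)
    rect(u)      = max(u, 0) / max|u|

Coupling through ``h`` alone yields a hole-like stripe pattern; through
``alpha`` alone, stripes form between dots but with the wrong orientation;
both together reproduce the four-species phenomenology (stripes between
dots, perpendicular to dot spacing).

The biharmonic operator -(1 + ell^2 lap)^2 is linear and is applied
spectrally by the solver; the functions here return only the local
(pointwise) part of each right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DomainMasks

COUPLING_MODES = ("none", "h_only", "alpha_only", "both")


@dataclass(frozen=True)
class SHDotParams:
    """Dot-field Swift-Hohenberg parameters."""

    alpha_dot: float = 0.2   # instability parameter (> 0 for dots)
    ell_dot: float = 3.2     # intrinsic length scale; dot spacing ~ 2 pi ell
    gamma: float = 1.2       # quadratic coefficient selecting dots over stripes
    k_deg_sh: float = 0.5    # decay of the dot field outside the domain

    def __post_init__(self) -> None:
        if self.ell_dot <= 0:
            raise ValueError(f"ell_dot must be positive, got {self.ell_dot}")
        if self.k_deg_sh < 0:
            raise ValueError("k_deg_sh must be non-negative")


@dataclass(frozen=True)
class SHStripeParams:
    """Stripe-field Swift-Hohenberg parameters (biased, rescaled in time)."""

    alpha0: float = 0.3      # baseline instability parameter
    ell_stripe: float = 2.0  # stripe length scale (about ell_dot / 1.6)
    h0: float = 0.3          # baseline additive bias
    tau: float = 1.0         # stripe timescale relative to the dot equation
    s_alpha: float = 0.8     # coupling slope on alpha
    s_h: float = 0.8         # coupling slope on h

    def __post_init__(self) -> None:
        if self.ell_stripe <= 0:
            raise ValueError(f"ell_stripe must be positive, got {self.ell_stripe}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass
class SHFields:
    """Sign-indefinite dot and stripe fields."""

    dot_field: np.ndarray
    stripe_field: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"dot_field": self.dot_field, "stripe_field": self.stripe_field}


def sh_dispersion(alpha: float, ell: float, k: np.ndarray | float) -> np.ndarray | float:
    """Linear growth rate alpha - (1 - ell^2 k^2)^2 of a Fourier mode.

    Maximized at the band centre k = 1/ell where it equals alpha.
    """
    if ell <= 0:
        raise ValueError(f"ell must be positive, got {ell}")
    k = np.asarray(k, float)
    out = alpha - (1.0 - ell**2 * k**2) ** 2
    return float(out) if out.ndim == 0 else out


def rect_normalized(u: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Rectified dot field scaled to [0, 1] by its spatial max amplitude."""
    scale = max(float(np.abs(u).max()), floor)
    return np.maximum(u, 0.0) / scale


def sh_dot_rhs(u: np.ndarray, p: SHDotParams, masks: DomainMasks) -> np.ndarray:
    """Local part of the dot equation (the biharmonic operator is spectral).

    Inside the domain: alpha u + gamma u^2 - u^3; outside: plain decay.
    """
    if not np.all(np.isfinite(u)):
        raise ValueError("dot field contains non-finite values")
    inside = masks.omega
    local = p.alpha_dot * u + p.gamma * u * u - u**3
    return np.where(inside, local, -p.k_deg_sh * u)


def sh_stripe_rhs(
    v: np.ndarray,
    u: np.ndarray,
    p: SHStripeParams,
    coupling_mode: str,
    masks: DomainMasks,
) -> np.ndarray:
    """Local part of tau * dv/dt (solver divides by tau and adds the operator).

    Outside the domain the growth and bias terms are dropped, so the stripe
    field relaxes to zero there under the biharmonic operator.
    """
    if coupling_mode not in COUPLING_MODES:
        raise ValueError(
            f"coupling_mode must be one of {COUPLING_MODES}, got {coupling_mode!r}"
        )
    if not np.all(np.isfinite(v)):
        raise ValueError("stripe field contains non-finite values")
    s_alpha = p.s_alpha if coupling_mode in ("alpha_only", "both") else 0.0
    s_h = p.s_h if coupling_mode in ("h_only", "both") else 0.0
    if s_alpha or s_h:
        r = rect_normalized(u)
        alpha_eff = p.alpha0 - s_alpha * r
        h_eff = p.h0 - s_h * r
    else:
        alpha_eff = p.alpha0
        h_eff = p.h0
    local = alpha_eff * v - v**3 + h_eff
    return np.where(masks.omega, local, -(v**3))
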