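"""Repair-misrepair-fixation (RMF) link from DSB induction to LQ survival.

Given a photon reference radiation with LQ parameters (α_γ, β_γ) and, for a
test radiation, the relative DSB yield RBE_DSB = Σ_p/Σ_γ and the
frequency-mean specific energy z̄F of the target, the RMF asymptotic limits
for reproductive cell death are

    RBE_LD = α_p/α_γ = RBE_DSB · (1 + 2·z̄F·RBE_DSB/(α/β)_γ)
    RBE_HD = √(β_p/β_γ) = RBE_DSB

Solving the two limits for the test radiation's LQ parameters:

    α_p = α_γ·RBE_DSB + 2·β_γ·RBE_DSB²·z̄F
    β_p = β_γ·RBE_DSB²

The low-dose limit exceeds the high-dose limit whenever z̄F > 0: the extra
linear killing is the inter-track-independent, intra-track (proximity)
contribution of densely spaced DSBs within single high-LET tracks.  Mixed
fields are aggregated by dose weighting of RBE_DSB and z̄F before applying
the formulas, and the photon-isoeffective dose at any absorbed dose follows
from equating LQ effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhotonReference",
    "RadiationComponent",
    "MixedField",
    "LQParameters",
    "RBEResult",
    "rbe_hd",
    "rbe_ld",
    "invert_zbarF",
    "lq_from_rmf",
    "dose_weighted_field",
    "rwd",
    "region_weighted_rbe",
    "survival",
    "isoeffective_dose",
]


@dataclass(frozen=True)
class PhotonReference:
    """Reference-radiation radiosensitivity (e.g. ⁶⁰Co γ-rays).

    Parameters
    ----------
    alpha_gamma, beta_gamma : float
        LQ parameters of the reference radiation, Gy⁻¹ and Gy⁻².
    sigma_gamma : float, optional
        Reference DSB yield Σ_γ in DSB·Gy⁻¹·Gbp⁻¹ (needed only for absolute
        per-track DSB counts).
    reference_correction : float
        Multiplicative factor applied to reported RBEs when the experimental
        reference differs from the modeling reference (e.g. 1.1 when survival
        was measured against 250 kVp X-rays rather than ⁶⁰Co). Applied
        explicitly, never silently; stored with every result.
    """

    alpha_gamma: float
    beta_gamma: float
    sigma_gamma: float | None = None
    reference_correction: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_gamma < 0:
            raise ValueError("alpha_gamma must be >= 0")
        if self.beta_gamma < 0:
            raise ValueError("beta_gamma must be >= 0")
        if self.reference_correction <= 0:
            raise ValueError("reference_correction must be positive")

    @property
    def ab_gamma(self) -> float:
        """(α/β)_γ in Gy."""
        if self.beta_gamma <= 0:
            raise ValueError("(α/β)_γ undefined: beta_gamma is zero")
        return self.alpha_gamma / self.beta_gamma

    @property
    def lq(self) -> "LQParameters":
        return LQParameters(self.alpha_gamma, self.beta_gamma)


@dataclass(frozen=True)
class RadiationComponent:
    """One ion contribution to a mixed field."""

    label: str
    dose: float  # absorbed dose, Gy
    rbe_dsb: float  # Σ_p/Σ_γ
    zbarF: float  # Gy

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"{self.label}: dose must be >= 0")
        if self.rbe_dsb <= 0:
            raise ValueError(f"{self.label}: rbe_dsb must be > 0")
        if self.zbarF < 0:
            raise ValueError(f"{self.label}: zbarF must be >= 0")


@dataclass(frozen=True)
class MixedField:
    """A mixed radiation field as a list of components."""

    components: tuple[RadiationComponent, ...]

    def __init__(self, components: Sequence[RadiationComponent]):
        object.__setattr__(self, "components", tuple(components))

    @property
    def total_dose(self) -> float:
        return sum(c.dose for c in self.components)

    def __iter__(self):
        return iter(self.components)

    def __len__(self):
        return len(self.components)


@dataclass(frozen=True)
class LQParameters:
    """Linear-quadratic survival parameters S = exp(−αD − βD²)."""

    alpha: float  # Gy^-1
    beta: float  # Gy^-2

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


@dataclass(frozen=True)
class RBEResult:
    """Dose-averaged RMF summary for a mixed field."""

    rbe_dsb_bar: float
    zbarF_bar: float
    rbe_ld: float
    rbe_hd: float
    lq: LQParameters
    reference_correction: float = 1.0


def rbe_hd(rbe_dsb: float) -> float:
    """High-dose RBE limit: identical to RBE_DSB (β_p/β_γ = RBE_DSB²)."""
    if rbe_dsb <= 0:
        raise ValueError(f"rbe_dsb must be positive, got {rbe_dsb}")
    return rbe_dsb


def rbe_ld(rbe_dsb: float, zbarF: float, ab_gamma: float) -> float:
    """Low-dose RBE limit RBE_DSB·(1 + 2·z̄F·RBE_DSB/(α/β)_γ)."""
    if rbe_dsb <= 0:
        raise ValueError(f"rbe_dsb must be positive, got {rbe_dsb}")
    if zbarF < 0:
        raise ValueError(f"zbarF must be non-negative, got {zbarF}")
    if ab_gamma <= 0:
        raise ValueError(f"(α/β)_γ must be positive, got {ab_gamma}")
    return rbe_dsb * (1.0 + 2.0 * zbarF * rbe_dsb / ab_gamma)


def invert_zbarF(rbe_dsb: float, rbe_ld_value: float, ab_gamma: float) -> float:
    """Solve the low-dose limit for z̄F given (RBE_DSB, RBE_LD, (α/β)_γ).

    z̄F = (α/β)_γ·(RBE_LD/RBE_DSB − 1)/(2·RBE_DSB); requires
    RBE_LD ≥ RBE_DSB (the limits bracket every attainable RBE).
    """
    if rbe_dsb <= 0 or ab_gamma <= 0:
        raise ValueError("rbe_dsb and ab_gamma must be positive")
    if rbe_ld_value < rbe_dsb:
        raise ValueError(
            f"RBE_LD ({rbe_ld_value}) < RBE_DSB ({rbe_dsb}): no valid z̄F")
    return ab_gamma * (rbe_ld_value / rbe_dsb - 1.0) / (2.0 * rbe_dsb)


def lq_from_rmf(
    ref: PhotonReference, rbe_dsb: float, zbarF: float
) -> LQParameters:
    """Test-radiation LQ parameters from the RMF asymptotic limits."""
    if rbe_dsb <= 0:
        raise ValueError(f"rbe_dsb must be positive, got {rbe_dsb}")
    if zbarF < 0:
        raise ValueError(f"zbarF must be non-negative, got {zbarF}")
    alpha_p = (ref.alpha_gamma * rbe_dsb
               + 2.0 * ref.beta_gamma * rbe_dsb**2 * zbarF)
    beta_p = ref.beta_gamma * rbe_dsb**2
    return LQParameters(alpha_p, beta_p)


def dose_weighted_field(field: MixedField, ref: PhotonReference) -> RBEResult:
    """Dose-averaged RBE_DSB and z̄F over a mixed field, with RMF limits.

    Per-component values are averaged with absorbed-dose weights
    (R̄ = Σ Dᵢ·Rᵢ / Σ Dᵢ, and z̄F likewise); the RMF formulas are then applied
    to the dose-averaged pair.  The reference correction multiplies the
    reported RBE limits and is recorded in the result.
    """
    if len(field) == 0:
        raise ValueError("empty component list")
    total = field.total_dose
    if total <= 0:
        raise ValueError("total dose must be positive for dose averaging")
    r_bar = sum(c.dose * c.rbe_dsb for c in field) / total
    z_bar = sum(c.dose * c.zbarF for c in field) / total
    corr = ref.reference_correction
    return RBEResult(
        rbe_dsb_bar=r_bar,
        zbarF_bar=z_bar,
        rbe_ld=corr * rbe_ld(r_bar, z_bar, ref.ab_gamma),
        rbe_hd=corr * rbe_hd(r_bar),
        lq=lq_from_rmf(ref, r_bar, z_bar),
        reference_correction=corr,
    )


def rwd(field: MixedField, per_component_rbe: Sequence[float]) -> float:
    """RBE-weighted dose Σᵢ RBEᵢ·Dᵢ (Gy-equivalent)."""
    if len(per_component_rbe) != len(field):
        raise ValueError(
            f"{len(per_component_rbe)} RBE values for {len(field)} components")
    return sum(r * c.dose for r, c in zip(per_component_rbe, field))


def region_weighted_rbe(regions: Sequence[tuple[float, float]]) -> float:
    """Overall RBE for several uniformly-dosed regions: Σ RWDⱼ / Σ Dⱼ."""
    total = sum(d for d, _ in regions)
    if total <= 0:
        raise ValueError("total dose over regions must be positive")
    return sum(r for _, r in regions) / total


def survival(lq: LQParameters, dose) -> float:
    """LQ surviving fraction exp(−αD − βD²)."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    s = np.exp(-lq.alpha * d - lq.beta * d**2)
    return float(s) if np.isscalar(dose) or d.ndim == 0 else s


def isoeffective_dose(
    lq_test: LQParameters, ref: PhotonReference, dose: float
) -> tuple[float, float]:
    """Photon-isoeffective dose D_γ and RBE(D) = D_γ/D at absorbed dose D.

    Solves α_γ·D_γ + β_γ·D_γ² = α_p·D + β_p·D² for the positive root with the
    numerically stable quadratic formula.  As D → 0 the RBE approaches the
    low-dose limit α_p/α_γ; as D → ∞ it approaches √(β_p/β_γ).  The reference
    correction multiplies the reported RBE (and hence D_γ).
    """
    if dose <= 0:
        raise ValueError(f"dose must be positive, got {dose}")
    effect = lq_test.alpha * dose + lq_test.beta * dose**2
    a_g, b_g = ref.alpha_gamma, ref.beta_gamma
    if b_g > 0:
        # stable positive root of b_g x^2 + a_g x - effect = 0
        d_gamma = 2.0 * effect / (a_g + math.sqrt(a_g**2 + 4.0 * b_g * effect))
    elif a_g > 0:
        d_gamma = effect / a_g
    else:
        raise ValueError("degenerate reference: alpha_gamma = beta_gamma = 0")
    d_gamma *= ref.reference_correction
    return d_gamma, d_gamma / dose
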