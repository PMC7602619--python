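"""Neutron-capture reaction source terms for BNCT dose components.

Thermal-neutron capture on ¹⁰B emits a back-to-back α/⁷Li pair; in ~94% of
captures the ⁷Li is left in its first excited state (α 1.47 MeV, ⁷Li
0.84 MeV, prompt 0.478 MeV γ) and in the remainder the pair shares the full
Q-value (α 1.78 MeV, ⁷Li 1.01 MeV).  Capture on tissue ¹⁴N emits a 0.59 MeV
proton with a ¹⁴C recoil.  These short-range products, together with fast
recoil protons from hydrogen elastic scattering and the photon background,
form the canonical dose components of a BNCT field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

from .microdosimetry import IonSpecies, PROTON, ALPHA, LI7, C14

__all__ = [
    "CaptureBranch",
    "DoseComponentSpec",
    "BORON_COMPONENT_NAMES",
    "boron_capture_branches",
    "nitrogen_capture_products",
    "component_catalog",
    "catalog_to_json",
]

#: Standard nuclear-data branching fraction to the ⁷Li excited state.
DEFAULT_EXCITED_FRACTION = 0.937

#: Kinematic constants for the two capture branches (MeV).
_EXCITED = (1.47, 0.84, 0.478)
_GROUND = (1.78, 1.01, 0.0)

#: ¹⁴N(n,p)¹⁴C proton energy (MeV).
NITROGEN_PROTON_MEV = 0.59

#: Component labels treated as boron-capture products by the pipeline.
BORON_COMPONENT_NAMES = ("boron_alpha", "boron_li")


@dataclass(frozen=True)
class CaptureBranch:
    """One ¹⁰B(n,α)⁷Li decay branch (energies in MeV)."""

    probability: float
    alpha_energy: float
    li_energy: float
    gamma_energy: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("branch probability must be in [0, 1]")
        if self.alpha_energy <= 0 or self.li_energy <= 0:
            raise ValueError("product energies must be positive")


@dataclass(frozen=True)
class DoseComponentSpec:
    """Canonical dose-component label with the ion it carries.

    ``ion`` is None for the photon component.
    """

    name: str
    ion: IonSpecies | None


def boron_capture_branches(
    excited_fraction: float = DEFAULT_EXCITED_FRACTION,
) -> list[CaptureBranch]:
    """The two ¹⁰B(n,α)⁷Li branches with configurable branching ratio.

    Within each branch the products are emitted back-to-back, so the energy
    partition obeys momentum conservation E_α/E_Li = m_Li/m_α = 7/4.
    """
    if not 0.0 <= excited_fraction <= 1.0:
        raise ValueError(
            f"excited_fraction must be in [0, 1], got {excited_fraction}")
    branches = []
    if excited_fraction > 0:
        branches.append(CaptureBranch(excited_fraction, *_EXCITED))
    if excited_fraction < 1:
        branches.append(CaptureBranch(1.0 - excited_fraction, *_GROUND))
    return branches


def nitrogen_capture_products() -> tuple[
    tuple[IonSpecies, float], tuple[IonSpecies, float]
]:
    """¹⁴N(n,p)¹⁴C products: 0.59 MeV proton and the momentum-matched recoil.

    The recoil kinetic energy follows from non-relativistic two-body momentum
    balance, E_C = E_p·(m_p/m_C); the implied Q-value (sum of the product
    energies) is a kinematic bookkeeping constant.
    """
    e_p = NITROGEN_PROTON_MEV
    e_c = e_p * PROTON.A / C14.A
    return (PROTON, e_p), (C14, e_c)


def component_catalog() -> list[DoseComponentSpec]:
    """Canonical BNCT dose components with ion metadata for RBE lookup."""
    return [
        DoseComponentSpec("boron_alpha", ALPHA),
        DoseComponentSpec("boron_li", LI7),
        DoseComponentSpec("nitrogen_proton", PROTON),
        DoseComponentSpec("hydrogen_recoil", PROTON),
        DoseComponentSpec("photon", None),
        DoseComponentSpec("heavy_ion", C14),
    ]


def catalog_to_json(path=None) -> str:
    """Export the component catalog as JSON (for pipeline configs)."""
    payload = [
        {"name": c.name,
         "ion": None if c.ion is None else asdict(c.ion)}
        for c in component_catalog()
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
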