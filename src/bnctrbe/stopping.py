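"""Synthetic stopping-power tables for the BNCT capture products.

These tables are synthetic: each ion's LET(E) grid is generated from a
one-parameter power-law range–energy model R(E) = a·E^b calibrated so that
the LET and CSDA range are exact at a single anchor energy characteristic of
that ion in BNCT fields (0.59 MeV protons from ¹⁴N capture, 1.47 MeV alphas
and 0.84 MeV ⁷Li recoils from ¹⁰B capture).  The identity LET(E)·R(E) = E/b
fixes b = E_a/(LET_a·R_a); LET(E) = E^(1−b)/(a·b) then varies smoothly over
decades of energy, which is all the chord-Monte-Carlo transport needs.  Real
evaluated tables (ICRU 49/73 or SRIM) should be substituted for quantitative
work on other ions or energy ranges.
"""

from __future__ import annotations

import numpy as np

from .microdosimetry import IonSpecies, PROTON, ALPHA, LI7, StoppingPowerTable

__all__ = ["ANCHORS", "power_law_table", "constant_let_table",
           "default_tables"]

#: Calibration anchors per ion symbol: (energy MeV, LET keV/µm, CSDA µm).
ANCHORS: dict[str, tuple[float, float, float]] = {
    "1H": (0.59, 38.03, 11.09),
    "4He": (1.47, 186.5, 8.28),
    "7Li": (0.84, 369.1, 4.18),
}


def power_law_table(
    ion: IonSpecies,
    anchor: tuple[float, float, float] | None = None,
    e_min: float = 1e-3,
    e_max: float = 10.0,
    n_points: int = 400,
) -> StoppingPowerTable:
    """Generate a synthetic LET(E) table from the power-law range model."""
    if anchor is None:
        try:
            anchor = ANCHORS[ion.symbol]
        except KeyError:
            raise KeyError(
                f"no built-in anchor for ion {ion.symbol}; pass one") from None
    e_a, let_a, r_a = anchor
    let_a_mev = let_a / 1000.0  # MeV/um
    b = e_a / (let_a_mev * r_a)
    a = r_a / e_a**b
    e = np.geomspace(e_min, e_max, n_points)
    let_mev_um = e ** (1.0 - b) / (a * b)
    return StoppingPowerTable(ion, energies=e, lets=let_mev_um * 1000.0)


def constant_let_table(
    ion: IonSpecies,
    let_kev_um: float,
    e_min: float = 1e-3,
    e_max: float = 1e3,
    n_points: int = 16,
) -> StoppingPowerTable:
    """Flat LET table (test fixture for the constant-LET crosser limit)."""
    e = np.geomspace(e_min, e_max, n_points)
    return StoppingPowerTable(
        ion, energies=e, lets=np.full_like(e, float(let_kev_um)))


def default_tables() -> dict[str, StoppingPowerTable]:
    """Synthetic tables for the three anchored capture-product ions."""
    return {
        "1H": power_law_table(PROTON),
        "4He": power_law_table(ALPHA),
        "7Li": power_law_table(LI7),
    }
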