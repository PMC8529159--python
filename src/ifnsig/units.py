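"""Unit conventions and conversion helpers.

Conventions used throughout the package:

* solution concentrations (ligand, dissociation constants ``K1``/``K2``) in molar;
  experimental doses in pM;
* surface densities (receptors, ternary complexes, in-membrane constants
  ``K3``/``K4``) in molecules per square micrometre;
* per-cell amounts ("copies") = density x membrane area;
* lengths in micrometres, areas in um^2, volumes in um^3; time in minutes.
"""

from __future__ import annotations

import math

AVOGADRO = 6.022_140_76e23  # 1/mol, exact

#: Reference reaction volume for converting a binding energy to a 3-D
#: dissociation constant, K = (1/v) exp(-E/kT) with v expressed in M^-1.
#: 1 M^-1 corresponds to 1 L/mol / N_A ~ 1.66 nm^3 per molecule.  Some sources
#: quote ~1.75 nm^3 for the same conversion; the constant is configurable
#: wherever it enters and the default follows the standard value.
STANDARD_VOLUME_M_INV = 1.0
STANDARD_VOLUME_NM3 = 1.0e24 / AVOGADRO  # ~1.6606 nm^3

#: Default molecular footprint for the analogous 2-D conversion
#: K_mem = (1/a) exp(-E/kT); 10 nm^2 is a typical protein-protein contact area.
DEFAULT_REACTION_AREA_NM2 = 10.0

PM_PER_M = 1.0e12
LITRES_PER_UM3 = 1.0e-15


def molar_to_pm(c: float) -> float:
    return c * PM_PER_M


def pm_to_molar(c: float) -> float:
    return c / PM_PER_M


def copies_to_nm(copies: float, volume_um3: float) -> float:
    """Convert a per-cell copy number to a cytoplasmic concentration in nM."""
    litres = volume_um3 * LITRES_PER_UM3
    return copies / (AVOGADRO * litres) * 1.0e9


def nm_to_copies(conc_nm: float, volume_um3: float) -> float:
    litres = volume_um3 * LITRES_PER_UM3
    return conc_nm * 1.0e-9 * AVOGADRO * litres


def membrane_scale(reaction_area_nm2: float = DEFAULT_REACTION_AREA_NM2,
                   reaction_volume_m_inv: float = STANDARD_VOLUME_M_INV) -> float:
    """Factor converting a solution K (molar) to its in-membrane analogue.

    With K3D = (1/v) e^{-E/kT} and K2D = (1/a) e^{-E/kT} for the same contact,
    the dimensionless Boltzmann factor is K3D [M] * v [M^-1], so
    K2D [um^-2] = (1/a) [um^-2] * v [M^-1] * K3D [M].  Returns (1/a) * v in
    molecules um^-2 per molar.
    """
    per_area = 1.0 / (reaction_area_nm2 * 1.0e-6)  # molecules per um^2
    return per_area * reaction_volume_m_inv


def sphere_area(radius_um: float) -> float:
    return 4.0 * math.pi * radius_um**2


def sphere_volume(radius_um: float) -> float:
    return (4.0 / 3.0) * math.pi * radius_um**3
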