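"""Core parameter containers for the receptor-assembly and pSTAT models.

The ternary IFN.IFNAR1.IFNAR2 complex can assemble along two paths (ligand
binds IFNAR1 first, or IFNAR2 first).  Thermodynamics links the four
dissociation constants through detailed balance, K1*K3 = K2*K4, because the
two paths form a closed cycle with no energy input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from . import units

_DB_RTOL = 1e-9


@dataclass(frozen=True)
class AffinitySet:
    """Ligand-receptor dissociation constants for one interferon.

    Parameters
    ----------
    K1, K2 : float
        Solution dissociation constants (molar) for IFN binding IFNAR1 and
        IFNAR2 respectively.
    K3, K4 : float
        In-membrane dissociation constants (molecules um^-2) for recruiting
        IFNAR2 into IFN.IFNAR1, and IFNAR1 into IFN.IFNAR2.
    usp18_fold : float, default 1
        Multiplier >= 1 applied to ``K4`` at evaluation time to represent
        USP18-destabilised IFNAR1 recruitment in primed cells.  A fold > 1 is
        a non-equilibrium perturbation: it deliberately breaks the detailed
        balance cycle, mirroring the biology (USP18 acts on the intracellular
        side of IFNAR2, increasing the ternary-complex off-rate).
    """

    K1: float
    K2: float
    K3: float
    K4: float
    usp18_fold: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        for label in ("K1", "K2", "K3", "K4"):
            if not getattr(self, label) > 0:
                raise ValueError(f"{label} must be strictly positive")
        if not self.usp18_fold >= 1.0:
            raise ValueError("usp18_fold must be >= 1")
        if self.usp18_fold == 1.0:
            lhs, rhs = self.K1 * self.K3, self.K2 * self.K4
            if abs(lhs - rhs) / lhs > _DB_RTOL:
                raise ValueError(
                    f"detailed balance violated: K1*K3={lhs:g} != K2*K4={rhs:g}"
                )

    @property
    def X(self) -> float:
        """Affinity ratio K2/K1 (read-only)."""
        return self.K2 / self.K1

    @property
    def K4_effective(self) -> float:
        """K4 including the USP18 priming fold."""
        return self.K4 * self.usp18_fold

    def perturb(self, ifnar1_affinity_fold: float = 1.0,
                ifnar2_affinity_fold: float = 1.0,
                usp18_fold: float | None = None,
                name: str | None = None) -> "AffinitySet":
        """Return a mutant/primed variant of this affinity set.

        A change in IFNAR1 binding energy moves ``K1`` and ``K4`` together; a
        change in IFNAR2 binding energy moves ``K2`` and ``K3`` together (this
        is how the R120A- and M148A-style ligand mutations act, and it
        preserves detailed balance).  ``usp18_fold`` is stored separately and
        applied to ``K4`` only when the model is evaluated.
        """
        if ifnar1_affinity_fold <= 0 or ifnar2_affinity_fold <= 0:
            raise ValueError("affinity folds must be strictly positive")
        if usp18_fold is None:
            usp18_fold = self.usp18_fold
        return AffinitySet(
            K1=self.K1 * ifnar1_affinity_fold,
            K2=self.K2 * ifnar2_affinity_fold,
            K3=self.K3 * ifnar2_affinity_fold,
            K4=self.K4 * ifnar1_affinity_fold,
            usp18_fold=usp18_fold,
            name=self.name if name is None else name,
        )


@dataclass(frozen=True)
class BindingEnergies:
    """Dimensionless binding energies of the ligand for the two subunits.

    ``E1_over_kT``/``E2_over_kT`` are the IFN-IFNAR1 / IFN-IFNAR2 binding
    energies in units of kT.  ``v`` (M^-1) and ``a`` (nm^2) are the reference
    reaction volume and area of the energy-to-affinity conversion.
    """

    E1_over_kT: float
    E2_over_kT: float
    v: float = units.STANDARD_VOLUME_M_INV
    a: float = units.DEFAULT_REACTION_AREA_NM2

    def __post_init__(self) -> None:
        if self.v <= 0 or self.a <= 0:
            raise ValueError("reaction volume and area must be positive")


def affinities_from_energies(be: BindingEnergies, name: str = "") -> AffinitySet:
    """Build an :class:`AffinitySet` from binding energies.

    K1 = (1/v) e^{-E1/kT}, K2 = (1/v) e^{-E2/kT},
    K4 = (1/a) e^{-E1/kT}, K3 = (1/a) e^{-E2/kT};
    detailed balance K1*K3 = K2*K4 holds identically.
    """
    boltz1 = math.exp(-be.E1_over_kT)
    boltz2 = math.exp(-be.E2_over_kT)
    inv_a = units.membrane_scale(be.a, be.v) / be.v  # (1/a) in um^-2
    return AffinitySet(
        K1=boltz1 / be.v,
        K2=boltz2 / be.v,
        K3=inv_a * boltz2,
        K4=inv_a * boltz1,
        name=name,
    )


def affinities_from_solution(K1: float, K2: float,
                             reaction_area_nm2: float = units.DEFAULT_REACTION_AREA_NM2,
                             reaction_volume_m_inv: float = units.STANDARD_VOLUME_M_INV,
                             name: str = "") -> AffinitySet:
    """Derive membrane constants from solution affinities via the energy map."""
    scale = units.membrane_scale(reaction_area_nm2, reaction_volume_m_inv)
    return AffinitySet(K1=K1, K2=K2, K3=scale * K2, K4=scale * K1, name=name)


@dataclass(frozen=True)
class ReceptorSurface:
    """IFNAR1/IFNAR2 surface densities in molecules um^-2."""

    R1: float
    R2: float

    def __post_init__(self) -> None:
        if self.R1 < 0 or self.R2 < 0:
            raise ValueError("receptor densities must be non-negative")
        if not self.RT > 0:
            raise ValueError("total receptor density must be positive")

    @property
    def RT(self) -> float:
        """Total surface density of both subunits."""
        return self.R1 + self.R2

    @property
    def delta(self) -> float:
        """Density difference R1 - R2 (|delta| <= RT by construction)."""
        return self.R1 - self.R2

    @classmethod
    def from_copies(cls, n1: float, n2: float, area_um2: float) -> "ReceptorSurface":
        return cls(n1 / area_um2, n2 / area_um2)


@dataclass(frozen=True)
class CellGeometry:
    """Spherical-cell geometry: radius (um), membrane area (um^2), volume (um^3)."""

    radius: float
    area: float
    volume: float

    @classmethod
    def from_radius(cls, radius_um: float) -> "CellGeometry":
        if radius_um <= 0:
            raise ValueError("radius must be positive")
        return cls(radius_um, units.sphere_area(radius_um),
                   units.sphere_volume(radius_um))

    @classmethod
    def from_area(cls, area_um2: float) -> "CellGeometry":
        r = math.sqrt(area_um2 / (4.0 * math.pi))
        return cls.from_radius(r)


@dataclass(frozen=True)
class PStatParams:
    """Aggregated STAT phosphorylation parameters.

    ``ST`` is the total STAT copy number per cell and ``Kp`` the ratio of the
    dephosphorylation to phosphorylation rate constants, expressed in copies,
    so that pSTAT = ST * (T*A) / (Kp + T*A) at steady state.
    """

    ST: float
    Kp: float

    def __post_init__(self) -> None:
        if self.ST <= 0 or self.Kp <= 0:
            raise ValueError("ST and Kp must be positive")

    def st_concentration_nm(self, geom: CellGeometry) -> float:
        """Total-STAT cytoplasmic concentration in nM."""
        return units.copies_to_nm(self.ST, geom.volume)

    @classmethod
    def from_concentration(cls, st_nm: float, Kp: float,
                           geom: CellGeometry) -> "PStatParams":
        return cls(units.nm_to_copies(st_nm, geom.volume), Kp)


def scaled(obj, **changes):
    """dataclasses.replace passthrough, re-running validation."""
    return replace(obj, **changes)
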