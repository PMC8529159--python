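"""Closed-form equilibrium model of ternary-complex assembly and pSTAT response.

The surface density of signalling-competent ternary complexes at ligand
concentration ``I`` is

    T(I) = (RT/2) * (Xi - sqrt(Xi^2 - 1 + (delta/RT)^2)),
    Xi(I) = 1 + (K4/RT) * (I + K1) * (I + K2) / (I * K1),

with RT = R1 + R2 and delta = R1 - R2 the total and difference of the subunit
surface densities.  T(I) is non-monotonic: it vanishes at I = 0, peaks at
Im = sqrt(K1*K2) and decays again at high dose (prozone: subunits sequestered
in binary complexes).  Below the peak the curve is well approximated by a
Michaelis-Menten form T ~ Tmax * I / (Keff + I).

Aggregated STAT phosphorylation by the ternary complex gives, at steady state,

    pSTAT = ST * T*A / (Kp + T*A)

with maximum ST * Tmax / (Tmax + Kp/A) and half-maximal ligand concentration
Keff / (1 + Tmax*A/Kp).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import AffinitySet, CellGeometry, PStatParams, ReceptorSurface

__all__ = [
    "ternary_complexes",
    "ternary_complexes_numeric",
    "tmax_imax",
    "keff",
    "mm_approximation",
    "pstat_equilibrium",
    "pstat_max",
    "pstat_ec50",
    "pstat_max_fold_change",
]


def _xi(aff: AffinitySet, surf: ReceptorSurface, I: float) -> float:
    k4 = aff.K4_effective
    return 1.0 + (k4 / surf.RT) * (I + aff.K1) * (I + aff.K2) / (I * aff.K1)


def ternary_complexes(aff: AffinitySet, surf: ReceptorSurface, I) -> float | np.ndarray:
    """Equilibrium ternary-complex surface density (molecules um^-2).

    ``I`` is the clamped extracellular ligand concentration in molar (scalar
    or array).  Returns 0 at I = 0; raises on negative I.
    """
    I_arr = np.asarray(I, dtype=float)
    if np.any(I_arr < 0):
        raise ValueError("ligand concentration must be non-negative")
    scalar = I_arr.ndim == 0
    I_arr = np.atleast_1d(I_arr)
    out = np.zeros_like(I_arr)
    pos = I_arr > 0
    if np.any(pos):
        Ip = I_arr[pos]
        k4 = aff.K4_effective
        xi = 1.0 + (k4 / surf.RT) * (Ip + aff.K1) * (Ip + aff.K2) / (Ip * aff.K1)
        disc = xi**2 - 1.0 + (surf.delta / surf.RT) ** 2
        if np.any(disc < 0):
            warnings.warn("clamping negative discriminant to zero (rounding)",
                          RuntimeWarning)
            disc = np.clip(disc, 0.0, None)
        # conjugate form of xi - sqrt(xi^2 - c), c = 1 - (delta/RT)^2: avoids
        # catastrophic cancellation at large xi (low/high dose limits)
        c = 1.0 - (surf.delta / surf.RT) ** 2
        out[pos] = 0.5 * surf.RT * c / (xi + np.sqrt(disc))
    return float(out[0]) if scalar else out


def ternary_complexes_numeric(aff: AffinitySet, surf: ReceptorSurface,
                              I: float) -> float:
    """Brute-force mass-action equilibrium, independent of the closed form.

    Solves the two conservation relations for the free subunit densities r1,
    r2 with the ligand clamped at ``I``:

        r1 * (1 + I/K1) + T = R1,   r2 * (1 + I/K2) + T = R2,
        T = (r2 * I / K2) * r1 / K4.

    USP18 priming scales both membrane constants (K3, K4) by the same fold so
    that the two assembly paths remain mutually consistent.  Root-finding via
    bisection on r2 (the residual is monotone).
    """
    if I < 0:
        raise ValueError("ligand concentration must be non-negative")
    if I == 0 or surf.R1 == 0 or surf.R2 == 0:
        return 0.0
    k4 = aff.K4 * aff.usp18_fold
    g = I / (aff.K2 * k4)  # T = g * r1 * r2
    s1 = 1.0 + I / aff.K1
    s2 = 1.0 + I / aff.K2

    def residual(r2: float) -> float:
        r1 = surf.R1 / (s1 + g * r2)
        return r2 * s2 + g * r1 * r2 - surf.R2

    lo, hi = 0.0, surf.R2 / s2
    r2 = brentq(residual, lo, hi, rtol=9e-16, xtol=hi * 1e-20 + 1e-300,
                maxiter=300)
    r1 = surf.R1 / (s1 + g * r2)
    return g * r1 * r2


def tmax_imax(aff: AffinitySet, surf: ReceptorSurface) -> tuple[float, float]:
    """Peak of the dose-response: (Tmax, Im) with Im = sqrt(K1*K2).

    At the peak, Xi is minimal: Xi_m = 1 + (K4/RT)*(1 + sqrt(K2/K1))^2.
    """
    im = math.sqrt(aff.K1 * aff.K2)
    return ternary_complexes(aff, surf, im), im


def keff(aff: AffinitySet, surf: ReceptorSurface,
         method: str = "closed_form") -> float:
    """Effective dissociation constant: T(Keff) = Tmax/2 on the rising branch.

    ``method="closed_form"`` inverts T(I) = Tmax/2 exactly.  Writing
    tau = 2T/RT and c = 1 - (delta/RT)^2, the branch relation
    Xi - sqrt(Xi^2 - c) = tau gives Xi = (tau^2 + c) / (2 tau), and
    Xi(I) = Xi_target reduces to a quadratic in I whose smaller root (below
    Im = sqrt(K1 K2)) is Keff.  ``method="numeric"`` bisects T(I) - Tmax/2 on
    (0, Im); both agree to machine precision and the numeric path is the
    fallback should the quadratic discriminant go negative by rounding.
    """
    tmax, im = tmax_imax(aff, surf)
    if method == "closed_form":
        tau = tmax / surf.RT  # = 2*(Tmax/2)/RT
        c = 1.0 - (surf.delta / surf.RT) ** 2
        xi_t = (tau**2 + c) / (2.0 * tau)
        k4 = aff.K4_effective
        b = (aff.K1 + aff.K2) - (xi_t - 1.0) * surf.RT * aff.K1 / k4
        disc = b * b - 4.0 * aff.K1 * aff.K2
        if disc < 0:
            warnings.warn("closed-form Keff discriminant < 0; using numeric",
                          RuntimeWarning)
            return keff(aff, surf, method="numeric")
        # smaller root via the product form (avoids cancellation: b < 0 and
        # |b| ~ sqrt(disc) whenever Keff << Im)
        return 2.0 * aff.K1 * aff.K2 / (-b + math.sqrt(disc))
    if method == "numeric":
        half = 0.5 * tmax
        lo = im * 1e-12
        return brentq(lambda I: ternary_complexes(aff, surf, I) - half,
                      lo, im, rtol=1e-14, xtol=im * 1e-18, maxiter=300)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class MMApproximation:
    value: float
    exact: float
    rel_deviation: float
    outside_validity: bool


def mm_approximation(aff: AffinitySet, surf: ReceptorSurface,
                     I: float) -> MMApproximation:
    """Michaelis-Menten approximation Tmax*I/(Keff+I), with its deviation.

    Valid on the rising branch (I < Im); evaluating beyond the peak sets the
    ``outside_validity`` flag instead of raising.
    """
    tmax, im = tmax_imax(aff, surf)
    ke = keff(aff, surf)
    approx = tmax * I / (ke + I) if I > 0 else 0.0
    exact = ternary_complexes(aff, surf, I)
    dev = abs(approx - exact) / exact if exact > 0 else 0.0
    return MMApproximation(approx, exact, dev, outside_validity=I >= im)


def pstat_equilibrium(aff: AffinitySet, surf: ReceptorSurface,
                      geom: CellGeometry, pp: PStatParams, I) -> float | np.ndarray:
    """Equilibrium pSTAT copies: ST * T*A / (Kp + T*A)."""
    T = ternary_complexes(aff, surf, I)
    tc = np.asarray(T) * geom.area
    out = pp.ST * tc / (pp.Kp + tc)
    return float(out) if np.ndim(I) == 0 else out


def pstat_max(aff: AffinitySet, surf: ReceptorSurface, geom: CellGeometry,
              pp: PStatParams) -> float:
    """Saturating pSTAT level, ST * Tmax / (Tmax + Kp/A) (copies)."""
    tmax, _ = tmax_imax(aff, surf)
    return pp.ST * tmax / (tmax + pp.Kp / geom.area)


def pstat_ec50(aff: AffinitySet, surf: ReceptorSurface, geom: CellGeometry,
               pp: PStatParams) -> float:
    """Half-maximal ligand concentration of the pSTAT response (molar).

    Keff / (1 + Tmax*A/Kp): unlike Keff itself this depends on the cell area,
    not only on the surface densities.
    """
    tmax, _ = tmax_imax(aff, surf)
    return keff(aff, surf) / (1.0 + tmax * geom.area / pp.Kp)


def pstat_max_fold_change(aff_a: AffinitySet, aff_b: AffinitySet,
                          surf: ReceptorSurface, geom: CellGeometry,
                          pp: PStatParams) -> float:
    """Ratio pSTATmax(a) / pSTATmax(b) between two ligands on the same cell.

    Equals (Tmax_a/Tmax_b) * (1 + Tmax_b/(Kp/A)) / (1 + Tmax_a/(Kp/A)): the
    full Tmax ratio survives when Kp/A is large, and the ratio tends to 1 when
    Kp/A is small (both ligands saturate STAT despite different Tmax).
    """
    ta, _ = tmax_imax(aff_a, surf)
    tb, _ = tmax_imax(aff_b, surf)
    q = pp.Kp / geom.area
    return (ta / tb) * (1.0 + tb / q) / (1.0 + ta / q)
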