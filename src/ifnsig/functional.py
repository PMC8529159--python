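"""Phenomenological mappings from pSTAT to downstream biological activity.

Anti-viral activity follows a Michaelis-Menten dependence on the pSTAT
concentration with a sub-picomolar constant (KM = 0.8 pM): nearly any pSTAT
saturates anti-viral gene induction, so all ligands can fully block viral
replication and the anti-viral IC50 sits far below the pSTAT EC50 (in the
KM/[ST] << 1 limit, IC50 ~ pSTAT_EC50 * KM/[ST]).

Anti-proliferative activity needs a mean of two Hill terms with constants on
the 100 pM scale (KM1 = 72 pM, KM2 = 158 pM, gamma1 = 0.9, gamma2 = 3.7) and
is evaluated on the USP18-primed pSTAT prediction, because the response
emerges on the ~24 h timescale where USP18 has accumulated.  There the
ligand-specific difference in saturating pSTAT translates into different
maximal activities: functional plasticity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

from . import equilibrium, units
from .params import AffinitySet


@dataclass(frozen=True)
class AntiviralParams:
    KM: float = 0.8  # pM

    def __post_init__(self) -> None:
        if self.KM <= 0:
            raise ValueError("KM must be positive")


@dataclass(frozen=True)
class AntiproliferativeParams:
    KM1: float = 72.0   # pM
    KM2: float = 158.0  # pM
    gamma1: float = 0.9
    gamma2: float = 3.7

    def __post_init__(self) -> None:
        if min(self.KM1, self.KM2, self.gamma1, self.gamma2) <= 0:
            raise ValueError("all anti-proliferative parameters must be positive")


def antiviral_activity(pstat_pm, p: AntiviralParams = AntiviralParams()):
    """Normalized anti-viral activity in [0, 1] for pSTAT concentration in pM."""
    x = np.asarray(pstat_pm, dtype=float)
    out = x / (p.KM + x)
    return float(out) if out.ndim == 0 else out


def antiproliferative_activity(pstat_primed_pm,
                               p: AntiproliferativeParams = AntiproliferativeParams()):
    """Normalized anti-proliferative activity (mean of two Hill terms).

    The input is the USP18-primed pSTAT concentration in pM.
    """
    x = np.asarray(pstat_primed_pm, dtype=float)
    with np.errstate(divide="ignore"):
        h1 = x**p.gamma1 / (p.KM1**p.gamma1 + x**p.gamma1)
        h2 = x**p.gamma2 / (p.KM2**p.gamma2 + x**p.gamma2)
    out = 0.5 * (h1 + h2)
    out = np.where(x == 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def pstat_copies_to_pm(copies, volume_um3: float):
    """Convert pSTAT copies to a cytoplasmic concentration in pM."""
    return np.asarray(copies) / (units.AVOGADRO * volume_um3
                                 * units.LITRES_PER_UM3) * 1.0e12


@dataclass(frozen=True)
class IC50Result:
    ic50: float | None
    plateau: float
    flag: str = ""


def ic50(dose_fn, lo: float, hi: float, rtol: float = 1e-6) -> IC50Result:
    """Half-maximal dose of a monotone dose->activity curve on [lo, hi].

    Half-max is defined relative to the curve's own plateau (its value at
    ``hi``).  Curves whose plateau does not reach twice the lowest value are
    flagged ``"no IC50"``.
    """
    top = dose_fn(hi)
    bottom = dose_fn(lo)
    if top <= 0 or (bottom > 0 and top < 2 * bottom):
        return IC50Result(None, top, "no IC50")
    half = 0.5 * top
    # bisection in log-dose space: dose scales span many decades and an
    # absolute tolerance in molar would dominate the answer
    u = brentq(lambda lg: dose_fn(math.exp(lg)) - half,
               math.log(lo), math.log(hi), xtol=rtol, maxiter=300)
    return IC50Result(float(math.exp(u)), float(top))


def ic50_from_table(doses, activity) -> IC50Result:
    """IC50 by monotone interpolation of tabulated (dose, activity) points."""
    doses = np.asarray(doses, dtype=float)
    activity = np.asarray(activity, dtype=float)
    order = np.argsort(doses)
    doses, activity = doses[order], activity[order]
    top = activity.max()
    if top <= 0 or (activity[0] > 0 and top < 2 * activity[0]):
        return IC50Result(None, top, "no IC50")
    half = 0.5 * top
    i = int(np.argmax(activity >= half))
    if i == 0:
        return IC50Result(float(doses[0]), float(top))
    x = np.interp(half, activity[i - 1:i + 1], doses[i - 1:i + 1])
    return IC50Result(float(x), float(top))


def fit_functional(doses_pm, measured, pstat_pm_fn, which: str = "antiviral",
                   gamma_bounds=(0.1, 10.0)):
    """Fit the mapping constants to (dose, activity) data, given a pSTAT model.

    ``pstat_pm_fn`` maps dose (pM) to pSTAT concentration (pM).  Bounded
    trust-region least squares; returns (params, rmse).
    """
    doses_pm = np.asarray(doses_pm, dtype=float)
    measured = np.asarray(measured, dtype=float)
    p = np.array([pstat_pm_fn(d) for d in doses_pm])

    if which == "antiviral":
        def resid(theta):
            return antiviral_activity(p, AntiviralParams(theta[0])) - measured
        res = least_squares(resid, x0=[1.0], bounds=([1e-6], [1e6]),
                            method="trf")
        params = AntiviralParams(float(res.x[0]))
    elif which == "antiproliferative":
        def resid(theta):
            return antiproliferative_activity(
                p, AntiproliferativeParams(*theta)) - measured
        res = least_squares(
            resid, x0=[50.0, 150.0, 1.0, 2.0],
            bounds=([1e-3, 1e-3, gamma_bounds[0], gamma_bounds[0]],
                    [1e6, 1e6, gamma_bounds[1], gamma_bounds[1]]),
            method="trf")
        params = AntiproliferativeParams(*map(float, res.x))
    else:
        raise ValueError(f"unknown mapping {which!r}")
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    rank_deficient = np.linalg.matrix_rank(res.jac) < res.x.size
    return params, rmse, rank_deficient


def k1k2_proxy(aff: AffinitySet) -> float:
    """K1*K2 (molar^2), the empirical proxy for Keff across ligands."""
    return aff.K1 * aff.K2


def proxy_diagnostic(base: AffinitySet, surf, k1_folds, k2_folds) -> dict:
    """Log-log regression of Keff on K1*K2 over an affinity sweep.

    Reports the regression slope, the Pearson correlation, and the maximum
    rank disagreement (bias): the proxy tracks Keff well overall but can
    mis-rank the highest-affinity ligands.
    """
    logs_proxy, logs_keff = [], []
    for f1 in k1_folds:
        for f2 in k2_folds:
            aff = base.perturb(ifnar1_affinity_fold=f1, ifnar2_affinity_fold=f2)
            logs_proxy.append(np.log10(k1k2_proxy(aff)))
            logs_keff.append(np.log10(equilibrium.keff(aff, surf)))
    x, y = np.asarray(logs_proxy), np.asarray(logs_keff)
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    rank_mismatch = int(np.sum(np.argsort(x) != np.argsort(y)))
    return {"slope": float(slope), "intercept": float(intercept),
            "pearson_r": r, "rank_mismatches": rank_mismatch}
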