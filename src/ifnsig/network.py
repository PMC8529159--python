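"""Mass-action ODE model of the IFN signalling network.

Species (per-cell copy numbers): free receptor subunits R1/R2, binary
complexes IFN.R1/IFN.R2, the ternary complex T, SOCS1-blocked counterparts of
every IFNAR1-containing surface species, internalized subunit pools, STAT,
pSTAT and free SOCS1.  Extracellular ligand is a clamped bath (no depletion).

Reactions: the two receptor-assembly paths, aggregate STAT phosphorylation by
unblocked ternary complexes, constitutive dephosphorylation, SOCS1 production
downstream of pSTAT with first-order decay, SOCS1 binding/unbinding to
IFNAR1-containing species (blocked complexes do not phosphorylate STAT),
basal internalization of free subunits, ligand-induced internalization of the
ternary complex (the internalized ligand is degraded; both subunits enter the
internal pools), and ligand-specific recycling back to the surface.  USP18
priming multiplies the single rate kd4 (IFNAR1 unbinding from the ternary
complex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from .params import AffinitySet, CellGeometry, PStatParams, ReceptorSurface
from . import defaults

SPECIES = ["R1", "R2", "B1", "B2", "T", "R1s", "B1s", "Ts",
           "R1i", "R2i", "STAT", "PSTAT", "SOCS"]
_IX = {name: i for i, name in enumerate(SPECIES)}

_DB_RTOL = 1e-9


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the network, consistent with an :class:`AffinitySet`.

    Solution association rates in M^-1 min^-1, membrane association in
    um^2 min^-1, all first-order rates in min^-1.  ``kd/ka`` ratios must
    reproduce K1..K4, and detailed balance K1*K3 = K2*K4 must hold whenever
    ``usp18_fold`` is 1.
    """

    ka1: float
    kd1: float
    ka2: float
    kd2: float
    ka3: float
    kd3: float
    ka4: float
    kd4: float
    kp_plus: float
    kp_minus: float
    k_socs: float = defaults.K_SOCS
    k_socs_decay: float = defaults.K_SOCS_DECAY
    k_socs_on: float = defaults.K_SOCS_ON
    k_socs_off: float = defaults.K_SOCS_OFF
    k_int_basal: float = defaults.K_INT_BASAL
    k_int_induced: float = 0.0
    k_rec1: float = 0.0
    k_rec2: float = 0.0
    usp18_fold: float = 1.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.usp18_fold == 1.0:
            lhs = (self.kd1 / self.ka1) * (self.kd3 / self.ka3)
            rhs = (self.kd2 / self.ka2) * (self.kd4 / self.ka4)
            if abs(lhs - rhs) / lhs > 1e-6:
                raise ValueError("rate constants violate detailed balance")

    @classmethod
    def from_affinities(cls, aff: AffinitySet, ligand: str | None = None,
                        ka_solution: float | None = None,
                        ka_membrane: float | None = None,
                        kp_minus: float | None = None,
                        kp_copies: float | None = None,
                        **feedback_rates) -> "KineticParameters":
        """Derive dissociation rates from the equilibrium constants.

        ``kp_copies`` sets kp_plus = kp_minus / Kp so the phosphorylation
        layer matches the equilibrium pSTAT model.  Ligand-specific
        internalization/recycling defaults are looked up by ``ligand`` name.
        """
        ka_solution = defaults.KA_SOLUTION if ka_solution is None else ka_solution
        ka_membrane = defaults.KA_MEMBRANE if ka_membrane is None else ka_membrane
        kp_minus = defaults.KP_MINUS if kp_minus is None else kp_minus
        kp_copies = defaults.KP_COPIES if kp_copies is None else kp_copies
        name = ligand or aff.name
        fb = dict(
            k_int_induced=defaults.K_INT_INDUCED.get(name, 0.02),
            k_rec1=defaults.K_REC1.get(name, 0.01),
            k_rec2=defaults.K_REC2.get(name, 0.01),
        )
        fb.update(feedback_rates)
        return cls(
            ka1=ka_solution, kd1=aff.K1 * ka_solution,
            ka2=ka_solution, kd2=aff.K2 * ka_solution,
            ka3=ka_membrane, kd3=aff.K3 * ka_membrane,
            ka4=ka_membrane, kd4=aff.K4 * ka_membrane,
            kp_plus=kp_minus / kp_copies, kp_minus=kp_minus,
            usp18_fold=aff.usp18_fold,
            **fb,
        )


@dataclass(frozen=True)
class Reaction:
    name: str
    rate_constant: float
    # indices of species whose copy numbers multiply the rate constant
    factors: tuple[int, ...]
    # net stoichiometry {species index: change}
    stoich: dict[int, int]
    # extra scalar multiplier (clamped ligand concentration, 1/area ...)
    prefactor: float = 1.0


@dataclass
class ReactionSystem:
    """Introspectable mass-action reaction system for one cell and one ligand."""

    kin: KineticParameters
    surf: ReceptorSurface
    geom: CellGeometry
    pp: PStatParams
    ligand_conc: float = 0.0  # molar, clamped
    reactions: list[Reaction] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.reactions = _build_reactions(self.kin, self.geom, self.ligand_conc)

    def with_ligand(self, I: float) -> "ReactionSystem":
        return ReactionSystem(self.kin, self.surf, self.geom, self.pp, I)

    # -- introspection ------------------------------------------------------
    def active_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.rate_constant * r.prefactor > 0]

    def stoichiometry_matrix(self) -> np.ndarray:
        n = np.zeros((len(SPECIES), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for i, s in r.stoich.items():
                n[i, j] = s
        return n

    def conservation_laws(self) -> np.ndarray:
        """Left null space of the stoichiometry matrix (rows = conserved sums)."""
        return null_space(self.stoichiometry_matrix().T).T

    def describe(self) -> str:
        lines = []
        for r in self.reactions:
            reac = " + ".join(SPECIES[i] for i, s in r.stoich.items() if s < 0) or "0"
            prod = " + ".join(SPECIES[i] for i, s in r.stoich.items() if s > 0) or "0"
            lines.append(f"{r.name}: {reac} -> {prod}   k = {r.rate_constant:g}")
        return "\n".join(lines)

    # -- initial condition --------------------------------------------------
    def initial_state(self) -> np.ndarray:
        x0 = np.zeros(len(SPECIES))
        x0[_IX["R1"]] = self.surf.R1 * self.geom.area
        x0[_IX["R2"]] = self.surf.R2 * self.geom.area
        x0[_IX["STAT"]] = self.pp.ST
        return x0


def _build_reactions(kin: KineticParameters, geom: CellGeometry,
                     I: float) -> list[Reaction]:
    ix = _IX
    A = geom.area
    rx: list[Reaction] = []

    def add(name, k, factors, stoich, pre=1.0):
        rx.append(Reaction(name, k, tuple(ix[f] for f in factors),
                           {ix[s]: v for s, v in stoich.items()}, pre))

    # receptor assembly (ligand clamped: enters as prefactor)
    add("bind_R1", kin.ka1, ("R1",), {"R1": -1, "B1": +1}, pre=I)
    add("unbind_B1", kin.kd1, ("B1",), {"B1": -1, "R1": +1})
    add("bind_R2", kin.ka2, ("R2",), {"R2": -1, "B2": +1}, pre=I)
    add("unbind_B2", kin.kd2, ("B2",), {"B2": -1, "R2": +1})
    add("recruit_R2", kin.ka3, ("B1", "R2"), {"B1": -1, "R2": -1, "T": +1},
        pre=1.0 / A)
    add("release_R2", kin.kd3, ("T",), {"T": -1, "B1": +1, "R2": +1})
    add("recruit_R1", kin.ka4, ("B2", "R1"), {"B2": -1, "R1": -1, "T": +1},
        pre=1.0 / A)
    add("release_R1", kin.kd4 * kin.usp18_fold, ("T",),
        {"T": -1, "B2": +1, "R1": +1})
    # STAT phosphorylation (catalysed by unblocked T)
    add("phosphorylate", kin.kp_plus, ("T", "STAT"), {"STAT": -1, "PSTAT": +1})
    add("dephosphorylate", kin.kp_minus, ("PSTAT",), {"PSTAT": -1, "STAT": +1})
    # SOCS1 feedback
    add("socs_production", kin.k_socs, ("PSTAT",), {"SOCS": +1})
    add("socs_decay", kin.k_socs_decay, ("SOCS",), {"SOCS": -1})
    for sp, blocked in (("R1", "R1s"), ("B1", "B1s"), ("T", "Ts")):
        add(f"socs_bind_{sp}", kin.k_socs_on, (sp, "SOCS"),
            {sp: -1, "SOCS": -1, blocked: +1})
        add(f"socs_unbind_{sp}", kin.k_socs_off, (blocked,),
            {blocked: -1, sp: +1, "SOCS": +1})
    # internalization and recycling
    add("internalize_R1", kin.k_int_basal, ("R1",), {"R1": -1, "R1i": +1})
    add("internalize_R2", kin.k_int_basal, ("R2",), {"R2": -1, "R2i": +1})
    add("internalize_T", kin.k_int_induced, ("T",),
        {"T": -1, "R1i": +1, "R2i": +1})
    add("recycle_R1", kin.k_rec1, ("R1i",), {"R1i": -1, "R1": +1})
    add("recycle_R2", kin.k_rec2, ("R2i",), {"R2i": -1, "R2": +1})
    return rx


def build_model(kin: KineticParameters, surf: ReceptorSurface,
                geom: CellGeometry, pp: PStatParams,
                ligand_conc: float = 0.0) -> ReactionSystem:
    """Assemble the reaction system for one cell; ligand is a clamped bath."""
    return ReactionSystem(kin, surf, geom, pp, ligand_conc)


def set_feedbacks(system: ReactionSystem, socs: bool = True,
                  internalization: bool = True,
                  usp18_fold: float | None = None) -> ReactionSystem:
    """Variant of ``system`` with feedback groups switched off or re-primed."""
    changes: dict = {}
    if not socs:
        changes.update(k_socs=0.0, k_socs_on=0.0)
    if not internalization:
        changes.update(k_int_basal=0.0, k_int_induced=0.0)
    if usp18_fold is not None:
        changes.update(usp18_fold=usp18_fold)
    kin = replace(system.kin, **changes)
    return ReactionSystem(kin, system.surf, system.geom, system.pp,
                          system.ligand_conc)


@dataclass
class Trajectory:
    """Simulated time course: time grid (min) and species copy numbers."""

    t: np.ndarray
    y: np.ndarray  # (n_species, n_times)
    ligand_conc: float
    solver_message: str = ""

    def species(self, name: str) -> np.ndarray:
        return self.y[_IX[name]]

    @property
    def pstat(self) -> np.ndarray:
        return self.species("PSTAT")

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.y.T, columns=SPECIES)
        df.insert(0, "time_min", self.t)
        return df


def _rhs_factory(reactions: list[Reaction]):
    ks = np.array([r.rate_constant * r.prefactor for r in reactions])
    factors = [np.array(r.factors, dtype=int) for r in reactions]
    n_sp = len(SPECIES)
    stoich = np.zeros((n_sp, len(reactions)))
    for j, r in enumerate(reactions):
        for i, s in r.stoich.items():
            stoich[i, j] = s

    def rhs(_t, x):
        v = ks.copy()
        for j, f in enumerate(factors):
            for i in f:
                v[j] *= x[i]
        return stoich @ v

    return rhs


def simulate(system: ReactionSystem, I: float | None = None,
             t_grid=None, rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the network from the resting state (all receptors free).

    Stiff-capable (LSODA).  Raises RuntimeError with the solver diagnostics on
    failure, and verifies the receptor and STAT conservation laws along the
    returned trajectory.
    """
    if I is not None:
        system = system.with_ligand(I)
    if t_grid is None:
        t_grid = np.array(defaults.TIMES_MIN)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    x0 = system.initial_state()
    t0 = 0.0 if t_grid[0] > 0 else t_grid[0]
    sol = solve_ivp(_rhs_factory(system.reactions), (t0, t_grid[-1]), x0,
                    method="LSODA", t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    _check_conservation(system, x0, y)
    return Trajectory(sol.t, y, system.ligand_conc, sol.message)


def _check_conservation(system: ReactionSystem, x0: np.ndarray,
                        y: np.ndarray, rtol: float = 1e-6) -> None:
    groups = {
        "R1": ["R1", "B1", "T", "R1s", "B1s", "Ts", "R1i"],
        "R2": ["R2", "B2", "T", "Ts", "R2i"],
        "STAT": ["STAT", "PSTAT"],
    }
    for label, members in groups.items():
        idx = [_IX[m] for m in members]
        total0 = x0[idx].sum()
        tot = y[idx].sum(axis=0)
        if total0 > 0 and np.max(np.abs(tot - total0)) / total0 > rtol:
            warnings.warn(f"conservation of total {label} drifted beyond rtol",
                          RuntimeWarning)


def steady_state(system: ReactionSystem, I: float, t_end: float = 5000.0,
                 **kw) -> np.ndarray:
    """Late-time state vector (used for equilibrium cross-checks)."""
    traj = simulate(system, I, np.array([t_end * 0.5, t_end]), **kw)
    return traj.y[:, -1]


def dose_response(system: ReactionSystem, doses, t: float,
                  t_grid=None, hill_summary: bool = True):
    """pSTAT at time ``t`` for each dose (molar, ascending), plus a Hill fit.

    Returns ``(pstat_per_dose, summary)`` where summary holds the fitted
    EC50 / max (None when no fit was requested or possible).
    """
    doses = np.asarray(list(doses), dtype=float)
    if doses.size == 0:
        return np.array([]), None
    if np.any(np.diff(doses) < 0):
        raise ValueError("doses must be sorted ascending")
    if t_grid is None:
        t_grid = np.unique(np.append(np.array(defaults.TIMES_MIN), t))
    out = np.empty(doses.size)
    for i, d in enumerate(doses):
        traj = simulate(system, d, t_grid)
        out[i] = np.interp(t, traj.t, traj.pstat)
    summary = fit_hill(doses, out) if hill_summary else None
    return out, summary


def fit_hill(doses: np.ndarray, response: np.ndarray) -> dict:
    """Least-squares Hill fit {max, ec50, n} of a dose-response curve."""
    from scipy.optimize import curve_fit

    def hill(x, top, ec50, n):
        return top * x**n / (ec50**n + x**n)

    pos = doses > 0
    try:
        p0 = [response.max(), np.median(doses[pos]), 1.0]
        popt, _ = curve_fit(hill, doses[pos], response[pos], p0=p0,
                            bounds=([0, 0, 0.2], [np.inf, np.inf, 5.0]),
                            maxfev=5000)
        return {"max": popt[0], "ec50": popt[1], "hill": popt[2]}
    except Exception:  # degenerate curves (all-zero response)
        return {"max": float(response.max(initial=0.0)), "ec50": np.nan,
                "hill": np.nan}
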