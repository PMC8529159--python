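"""Ligand-discrimination analysis.

Quantifies how far ligand identity can be read out independently of dose:

* the *absolute discrimination region* — the band of saturating pSTAT levels
  only the stronger-binding ligand can reach at any dose;
* the early/late *time-course* scatter — sustained vs transient character per
  (ligand, dose), and whether the two ligands separate;
* *feedback dissection* — how SOCS1, receptor internalization and USP18
  priming reshape the inter-ligand response ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import defaults, equilibrium, network, population


@dataclass(frozen=True)
class DiscriminationRegion:
    lower: float       # saturating response of the weaker ligand
    upper: float       # saturating response of the stronger ligand
    stronger: str
    flagged: bool = False

    @property
    def width(self) -> float:
        return max(0.0, self.upper - self.lower)


def absolute_discrimination_region(curve_a, curve_b, names=("a", "b"),
                                   saturation_rtol: float = 0.05
                                   ) -> DiscriminationRegion:
    """Region bounds from two dose-response curves sampled at shared doses.

    Each curve is a (doses, response) pair evaluated up to a saturating dose
    (>= 10x the weaker binder's Keff).  Responses inside the returned band
    identify the stronger binder unambiguously.  Curves still rising at the
    top dose are flagged.
    """
    (da, ra), (db, rb) = curve_a, curve_b
    tops = []
    flagged = False
    for d, r in ((np.asarray(da, float), np.asarray(ra, float)),
                 (np.asarray(db, float), np.asarray(rb, float))):
        top = float(r.max())  # plateau = the curve's achieved maximum
        if r.size >= 2 and top > 0:
            slope = abs(r[-1] - r[-2]) / top
            flagged |= slope > saturation_rtol and r[-1] > r[-2]
        tops.append(top)
    hi, lo = max(tops), min(tops)
    stronger = names[int(np.argmax(tops))]
    return DiscriminationRegion(lo, hi, stronger, flagged)


def saturating_dose_pm(ligands: dict, surf, factor: float = 10.0) -> float:
    """factor x Keff of the weaker binder, in pM (the shared saturating dose)."""
    keffs = [equilibrium.keff(aff, surf) for aff in ligands.values()]
    return max(keffs) * factor * 1e12


@dataclass
class TimeCourseVerdict:
    records: pd.DataFrame
    separable_doses: list[float]
    verdict: str
    threshold: float


def time_course_scatter(panel: pd.DataFrame,
                        t_early: float = defaults.T_EARLY_MIN,
                        t_late: float = defaults.T_LATE_MIN,
                        sustained_threshold: float = 0.2) -> TimeCourseVerdict:
    """Early/late scatter per (ligand, dose) with a separability verdict.

    The time-course index late/early classifies each point as sustained
    (|index - 1| <= threshold) or transient.  Ligands "separate" at a dose if
    their index intervals (mean +/- SD across replicates) do not overlap; the
    overall verdict is "separable" only if that holds at every dose (the
    per-dose list is also returned, since separation can be confined to a
    narrow window of intermediate concentrations).
    """
    col = "mfi" if "mfi" in panel.columns else "mean_mfi"
    times = set(panel["time_min"].unique())
    missing = {t_early, t_late} - times
    if missing:
        raise ValueError(f"panel lacks required time points: {sorted(missing)}")
    sub = panel[panel["time_min"].isin([t_early, t_late])]
    grouped = (sub.groupby(["ligand", "dose_pM", "time_min"])[col]
               .agg(["mean", "std"]).reset_index().fillna(0.0))
    wide = grouped.pivot(index=["ligand", "dose_pM"], columns="time_min")
    records = []
    for (ligand, dose), row in wide.iterrows():
        early, late = row[("mean", t_early)], row[("mean", t_late)]
        if early <= 0:
            continue
        idx = late / early
        sd = idx * np.sqrt((row[("std", t_early)] / early) ** 2
                           + (row[("std", t_late)] / max(late, 1e-300)) ** 2)
        records.append({
            "ligand": ligand, "dose_pM": dose, "early": early, "late": late,
            "index": idx, "index_sd": sd,
            "character": ("sustained" if abs(idx - 1.0) <= sustained_threshold
                          else "transient"),
        })
    rec = pd.DataFrame(records)
    separable_doses = []
    for dose, grp in rec.groupby("dose_pM"):
        if len(grp) < 2:
            continue
        ivals = [(r["index"] - r["index_sd"], r["index"] + r["index_sd"])
                 for _, r in grp.iterrows()]
        lo = max(a for a, _ in ivals)
        hi = min(b for _, b in ivals)
        if lo > hi:  # intervals disjoint
            separable_doses.append(float(dose))
    verdict = ("separable" if separable_doses and
               len(separable_doses) == rec["dose_pM"].nunique()
               else "not separable")
    return TimeCourseVerdict(rec, separable_doses, verdict, sustained_threshold)


FEEDBACK_CONDITIONS = {
    "none": dict(socs=False, internalization=False),
    "socs_only": dict(socs=True, internalization=False),
    "internalization_only": dict(socs=False, internalization=True),
    "both": dict(socs=True, internalization=True),
}


def feedback_dissection(config: population.ModelConfig, doses_pm, t: float,
                        surf=None, usp18_fold: float | None = None
                        ) -> pd.DataFrame:
    """Saturating pSTAT per ligand under each feedback configuration.

    Single-cell (median receptor) dissection: rows are feedback conditions,
    with the per-ligand pSTAT at time ``t`` at the top dose and the
    inter-ligand ratio (first ligand / second).
    """
    names = list(config.ligands)
    if surf is None:
        surf = population.sample_receptors(
            type(config.population)(median_r1=config.population.median_r1,
                                    median_r2=config.population.median_r2,
                                    sigma1=0.0, sigma2=0.0, n_cells=1),
            config.geom, seed=0)[0]
    doses_m = np.asarray(sorted(doses_pm), dtype=float) / 1e12
    rows = []
    for cond, switches in FEEDBACK_CONDITIONS.items():
        vals = {}
        for name in names:
            system = network.build_model(config.kinetics[name], surf,
                                         config.geom, config.pp)
            system = network.set_feedbacks(system, usp18_fold=usp18_fold,
                                           **switches)
            resp, _ = network.dose_response(system, doses_m, t,
                                            hill_summary=False)
            vals[name] = resp[-1]
        row = {"condition": cond, **{f"pstat_{n}": vals[n] for n in names}}
        if len(names) >= 2:
            row["ratio"] = vals[names[0]] / vals[names[1]]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class DiscriminationReport:
    """Bundle of per-ligand metrics and condition tables."""

    per_ligand: pd.DataFrame
    region: DiscriminationRegion
    region_primed: DiscriminationRegion | None = None
    feedback_table: pd.DataFrame | None = None
    time_course: TimeCourseVerdict | None = None


def equilibrium_report(config: population.ModelConfig, surf=None,
                       usp18_fold: float = defaults.USP18_FOLD_PRIMED
                       ) -> DiscriminationReport:
    """Equilibrium-level discrimination summary (pSTATmax, EC50, regions)."""
    if surf is None:
        surf = population.ReceptorSurface.from_copies(
            config.population.median_r1, config.population.median_r2,
            config.geom.area)
    rows = []
    curves = {}
    for primed in (False, True):
        for name, aff in config.ligands.items():
            a = aff if not primed else aff.perturb(usp18_fold=usp18_fold)
            pmax = equilibrium.pstat_max(a, surf, config.geom, config.pp)
            ec50 = equilibrium.pstat_ec50(a, surf, config.geom, config.pp)
            rows.append({"ligand": name, "primed": primed,
                         "pstat_max": pmax, "ec50_molar": ec50})
            curves[(name, primed)] = pmax
    df = pd.DataFrame(rows)

    def region(primed):
        tops = {n: curves[(n, primed)] for n in config.ligands}
        names = list(tops)
        vals = [tops[n] for n in names]
        hi, lo = max(vals), min(vals)
        return DiscriminationRegion(lo, hi, names[int(np.argmax(vals))])

    return DiscriminationReport(df, region(False), region(True))
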