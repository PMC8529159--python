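"""Cell-to-cell receptor heterogeneity and population-averaged MFI readouts.

Flow-cytometry MFI reflects a population average over cells whose IFNAR1 and
IFNAR2 copy numbers vary log-normally.  Predictions therefore sample receptor
levels per cell, run the single-cell model, average pSTAT over the sample and
apply a global molecules-to-MFI scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import defaults, equilibrium, network
from .params import AffinitySet, CellGeometry, PStatParams, ReceptorSurface


@dataclass(frozen=True)
class PopulationSpec:
    """Log-normal receptor heterogeneity across cells.

    Parameterized by the median copy number and the natural-log SD so that
    ``sigma = 0`` reduces exactly to the median cell.  ``corr`` optionally
    correlates the IFNAR1 and IFNAR2 draws (independent by default).
    """

    median_r1: float = defaults.RECEPTOR_MEDIAN_COPIES
    median_r2: float = defaults.RECEPTOR_MEDIAN_COPIES
    sigma1: float = defaults.RECEPTOR_LOG_SD
    sigma2: float = defaults.RECEPTOR_LOG_SD
    n_cells: int = defaults.N_CELLS
    mfi_scale: float = defaults.MFI_SCALE
    corr: float = 0.0
    size_classes: tuple = (("small", defaults.SMALL_CELL_RADIUS_UM),
                           ("large", defaults.LARGE_CELL_RADIUS_UM))

    def __post_init__(self) -> None:
        if self.median_r1 <= 0 or self.median_r2 <= 0:
            raise ValueError("receptor medians must be positive")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("log-SDs must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.mfi_scale <= 0:
            raise ValueError("mfi_scale must be positive")
        if not -1.0 < self.corr < 1.0:
            raise ValueError("corr must lie in (-1, 1)")


def sample_receptors(spec: PopulationSpec, geom: CellGeometry,
                     seed: int | np.random.Generator = 0) -> list[ReceptorSurface]:
    """Draw per-cell receptor surfaces (copies -> densities via the cell area)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z1 = rng.standard_normal(spec.n_cells)
    z2 = rng.standard_normal(spec.n_cells)
    z2 = spec.corr * z1 + np.sqrt(1.0 - spec.corr**2) * z2
    n1 = spec.median_r1 * np.exp(spec.sigma1 * z1)
    n2 = spec.median_r2 * np.exp(spec.sigma2 * z2)
    return [ReceptorSurface.from_copies(a, b, geom.area) for a, b in zip(n1, n2)]


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to predict a single cell's pSTAT response."""

    ligands: dict[str, AffinitySet]
    geom: CellGeometry
    pp: PStatParams
    population: PopulationSpec
    kinetics: dict[str, network.KineticParameters] = field(default_factory=dict)

    @classmethod
    def default(cls, **overrides) -> "ModelConfig":
        geom = overrides.pop("geom", defaults.DEFAULT_GEOMETRY)
        ligands = overrides.pop("ligands", dict(defaults.DEFAULT_LIGANDS))
        pp = overrides.pop("pp", defaults.default_pstat_params(geom))
        pop = overrides.pop("population", PopulationSpec())
        kin = overrides.pop("kinetics", None) or {
            name: network.KineticParameters.from_affinities(aff, name,
                                                            kp_copies=pp.Kp)
            for name, aff in ligands.items()
        }
        if overrides:
            raise TypeError(f"unknown overrides: {sorted(overrides)}")
        return cls(ligands, geom, pp, pop, kin)

    def with_usp18(self, fold: float) -> "ModelConfig":
        ligands = {n: replace(a, usp18_fold=fold) for n, a in self.ligands.items()}
        kin = {n: replace(k, usp18_fold=fold) for n, k in self.kinetics.items()}
        return replace(self, ligands=ligands, kinetics=kin)


def size_scaled_configuration(config: ModelConfig, radius_um: float) -> ModelConfig:
    """Rescale a configuration to a different cell radius.

    Receptor copy numbers scale with the membrane area (r^2) and total STAT
    with the cytoplasmic volume (r^3), keeping surface receptor density and
    cytoplasmic STAT concentration constant; rate constants are untouched.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    geom = CellGeometry.from_radius(radius_um)
    area_ratio = geom.area / config.geom.area
    vol_ratio = geom.volume / config.geom.volume
    pop = replace(config.population,
                  median_r1=config.population.median_r1 * area_ratio,
                  median_r2=config.population.median_r2 * area_ratio)
    pp = PStatParams(config.pp.ST * vol_ratio, config.pp.Kp)
    return replace(config, geom=geom, pp=pp, population=pop)


def _cell_pstat_kinetic(config: ModelConfig, ligand: str,
                        surf: ReceptorSurface, doses_m, times) -> np.ndarray:
    kin = config.kinetics[ligand]
    system = network.build_model(kin, surf, config.geom, config.pp)
    out = np.empty((len(doses_m), len(times)))
    t_grid = np.unique(np.asarray(times, dtype=float))
    for i, dose in enumerate(doses_m):
        traj = network.simulate(system, dose, t_grid)
        out[i] = np.interp(times, traj.t, traj.pstat)
    return out


def _cell_pstat_equilibrium(config: ModelConfig, ligand: str,
                            surf: ReceptorSurface, doses_m, times) -> np.ndarray:
    aff = config.ligands[ligand]
    p = equilibrium.pstat_equilibrium(aff, surf, config.geom, config.pp,
                                      np.asarray(doses_m, dtype=float))
    return np.tile(np.atleast_1d(p)[:, None], (1, len(times)))


def population_response(config: ModelConfig, doses_pm, times_min,
                        ligands=None, seed: int = 0,
                        predictor: str = "kinetic",
                        keep_cells: bool = False) -> pd.DataFrame:
    """Mean MFI table over the sampled population.

    Returns a long-format frame (ligand, dose_pM, time_min, mean_mfi, n_cells)
    with MFI = mean pSTAT copies x mfi_scale.  ``predictor`` selects the
    kinetic ODE model or the (steady-state, feedback-free) equilibrium model.
    A failed cell simulation aborts the panel, identifying the cell.
    """
    if predictor not in ("kinetic", "equilibrium"):
        raise ValueError(f"unknown predictor {predictor!r}")
    ligands = list(ligands or config.ligands)
    doses_pm = np.asarray(list(doses_pm), dtype=float)
    times = np.asarray(list(times_min), dtype=float)
    doses_m = doses_pm / 1e12
    cells = sample_receptors(config.population, config.geom, seed)
    records = []
    per_cell = []
    for ligand in ligands:
        acc = np.zeros((doses_m.size, times.size))
        for ci, surf in enumerate(cells):
            try:
                if predictor == "kinetic":
                    p = _cell_pstat_kinetic(config, ligand, surf, doses_m, times)
                else:
                    p = _cell_pstat_equilibrium(config, ligand, surf, doses_m, times)
            except Exception as err:
                raise RuntimeError(
                    f"cell {ci} (ligand {ligand}) failed: {err}") from err
            acc += p
            if keep_cells:
                per_cell.append((ligand, ci, p))
        mean = acc / len(cells) * config.population.mfi_scale
        for i, d in enumerate(doses_pm):
            for j, t in enumerate(times):
                records.append((ligand, d, t, mean[i, j], len(cells)))
    df = pd.DataFrame(records,
                      columns=["ligand", "dose_pM", "time_min", "mean_mfi",
                               "n_cells"])
    if keep_cells:
        df.attrs["per_cell"] = per_cell
    return df
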