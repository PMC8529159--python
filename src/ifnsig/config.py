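"""Structured run configuration (YAML) with schema validation."""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import defaults, population, synthetic
from .params import AffinitySet, CellGeometry, PStatParams, affinities_from_solution


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LigandConfig(_Strict):
    K1: float = Field(gt=0)
    K2: float = Field(gt=0)
    K3: Optional[float] = Field(default=None, gt=0)
    K4: Optional[float] = Field(default=None, gt=0)
    ifnar1_affinity_fold: float = Field(default=1.0, gt=0)
    ifnar2_affinity_fold: float = Field(default=1.0, gt=0)
    usp18_fold: float = Field(default=1.0, ge=1.0)

    def build(self, name: str) -> AffinitySet:
        if (self.K3 is None) != (self.K4 is None):
            raise ValueError(f"ligand {name}: give both K3 and K4 or neither")
        if self.K3 is None:
            aff = affinities_from_solution(self.K1, self.K2, name=name)
        else:
            aff = AffinitySet(self.K1, self.K2, self.K3, self.K4, name=name)
        return aff.perturb(self.ifnar1_affinity_fold, self.ifnar2_affinity_fold,
                           usp18_fold=self.usp18_fold)


class CellConfig(_Strict):
    radius_um: float = Field(default=defaults.SMALL_CELL_RADIUS_UM, gt=0)
    receptor_median_r1: float = Field(default=defaults.RECEPTOR_MEDIAN_COPIES, gt=0)
    receptor_median_r2: float = Field(default=defaults.RECEPTOR_MEDIAN_COPIES, gt=0)
    receptor_log_sd: float = Field(default=defaults.RECEPTOR_LOG_SD, ge=0)
    st_concentration_nm: float = Field(default=defaults.ST_CONCENTRATION_NM, gt=0)
    kp_copies: float = Field(default=defaults.KP_COPIES, gt=0)


class PopulationConfig(_Strict):
    n_cells: int = Field(default=defaults.N_CELLS, ge=1)
    mfi_scale: float = Field(default=defaults.MFI_SCALE, gt=0)
    corr: float = Field(default=0.0, gt=-1.0, lt=1.0)


class ScenarioConfig(_Strict):
    kind: str = "dose_time_panel"
    doses_pm: list[float] = Field(default_factory=lambda: list(defaults.DOSES_PM))
    times_min: list[float] = Field(default_factory=lambda: list(defaults.TIMES_MIN))
    replicates: int = Field(default=3, ge=1)
    noise_cv: float = Field(default=0.2, ge=0)
    predictor: str = "kinetic"
    usp18_fold: float = Field(default=defaults.USP18_FOLD_PRIMED, ge=1.0)


class InferenceConfig(_Strict):
    free: list[str] = Field(default_factory=lambda: ["receptor_median", "kp"])
    bounds: dict[str, tuple[float, float]] = Field(default_factory=dict)
    predictor: str = "equilibrium"
    chains: int = 4
    steps: int = 5000
    burn_in: int = 1000


class RunConfig(_Strict):
    """Top-level, schema-validated run configuration."""

    seed: int = 0
    ligands: dict[str, LigandConfig] = Field(default_factory=dict)
    cell: CellConfig = Field(default_factory=CellConfig)
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    inference: InferenceConfig = Field(default_factory=InferenceConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except ValidationError as err:
            first = err.errors()[0]
            key = ".".join(str(p) for p in first["loc"])
            raise ValueError(
                f"invalid configuration key '{key}': {first['msg']}") from err

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)

    # -- builders -----------------------------------------------------------
    def build_model_config(self) -> population.ModelConfig:
        geom = CellGeometry.from_radius(self.cell.radius_um)
        ligands = ({n: c.build(n) for n, c in self.ligands.items()}
                   or dict(defaults.DEFAULT_LIGANDS))
        pp = PStatParams.from_concentration(self.cell.st_concentration_nm,
                                            self.cell.kp_copies, geom)
        pop = population.PopulationSpec(
            median_r1=self.cell.receptor_median_r1,
            median_r2=self.cell.receptor_median_r2,
            sigma1=self.cell.receptor_log_sd,
            sigma2=self.cell.receptor_log_sd,
            n_cells=self.population.n_cells,
            mfi_scale=self.population.mfi_scale,
            corr=self.population.corr,
        )
        from .network import KineticParameters
        kin = {n: KineticParameters.from_affinities(a, n, kp_copies=pp.Kp)
               for n, a in ligands.items()}
        return population.ModelConfig(ligands, geom, pp, pop, kin)

    def build_scenario(self, seed: int | None = None) -> synthetic.ScenarioSpec:
        s = self.scenario
        return synthetic.ScenarioSpec(
            kind=s.kind, doses_pm=tuple(s.doses_pm),
            times_min=tuple(s.times_min), replicates=s.replicates,
            noise_cv=s.noise_cv, predictor=s.predictor,
            usp18_fold=s.usp18_fold,
            seed=self.seed if seed is None else seed)
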