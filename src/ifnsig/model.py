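"""statsmodels-style modelling surface: build a model from a panel, fit it,
inspect a results object.

Example
-------
>>> from ifnsig import synthetic, model
>>> panel = synthetic.generate(synthetic.ScenarioSpec(
...     kind="dose_time_panel", predictor="equilibrium", noise_cv=0.0))
>>> m = model.PStatResponseModel.from_panel(
...     panel, free=("receptor_median", "kp"),
...     bounds={"receptor_median": (100, 10000), "kp": (50, 10000)})
>>> res = m.fit()
>>> print(res.summary())      # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import inference, population, synthetic

DEFAULT_BOUNDS = {
    "receptor_median": (50.0, 5.0e4),
    "kp": (10.0, 1.0e5),
    "st": (50.0, 1.0e5),
    "mfi_scale": (0.1, 100.0),
}


class PStatResponseModel:
    """pSTAT dose-time response model bound to an observed panel.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format records with columns ligand, dose_pM, time_min, mfi
        (replicate/cell_class optional).
    config : ModelConfig
        Mechanistic configuration supplying every non-free parameter.
    free : sequence of str
        Free-parameter names (see :func:`ifnsig.inference.apply_free_params`).
    bounds : dict, optional
        Per-parameter (lo, hi); defaults cover the registry parameters.
    predictor : {"equilibrium", "kinetic"}
        Steady-state closed form, or the full ODE network.
    """

    def __init__(self, data: pd.DataFrame, config=None,
                 free=("receptor_median", "kp"), bounds=None,
                 predictor: str = "equilibrium", **fit_options):
        self.data = data.copy()
        self.config = config or population.ModelConfig.default()
        bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
        missing = [p for p in free if p not in bounds and ":" not in p]
        if missing:
            raise KeyError(f"no bounds for free parameters: {missing}")
        for p in free:
            bounds.setdefault(p, (1e-6, 1e3))  # ligand-rate fallback
        self.spec = inference.FitSpec(free=tuple(free),
                                      bounds={p: bounds[p] for p in free},
                                      predictor=predictor, **fit_options)

    @classmethod
    def from_panel(cls, panel: synthetic.ResponsePanel, **kw) -> "PStatResponseModel":
        return cls(panel.data, **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "PStatResponseModel":
        return cls(df, **kw)

    # -- estimation ---------------------------------------------------------
    def fit(self, **overrides) -> "PStatResponseResults":
        spec = replace(self.spec, **overrides) if overrides else self.spec
        point = inference.fit_point(self.data, self.config, spec)
        return PStatResponseResults(self, spec, point)

    def fit_mcmc(self, **overrides) -> "PStatResponseResults":
        spec = replace(self.spec, **overrides) if overrides else self.spec
        point = inference.fit_point(self.data, self.config, spec)
        chains = inference.fit_mcmc(self.data, self.config, spec)
        return PStatResponseResults(self, spec, point, chains)

    def predict(self, values=None, params: dict | None = None) -> pd.DataFrame:
        if params is not None:
            values = [params[p] for p in self.spec.free]
        predictor = inference.PanelPredictor(self.data, self.config, self.spec)
        return predictor(values).rename(columns={"pred": "mean_mfi"})


@dataclass
class PStatResponseResults:
    """Estimates, uncertainty and diagnostics for a fitted response model."""

    model: PStatResponseModel
    spec: inference.FitSpec
    point: inference.PointFit
    chains: inference.McmcResult | None = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.point.params, name="estimate")

    @property
    def loss(self) -> float:
        return self.point.loss

    def conf_int(self, level: float = 0.9) -> pd.DataFrame:
        if self.chains is None:
            raise ValueError("run fit_mcmc() for posterior intervals")
        iv = self.chains.interval(level)
        return pd.DataFrame(iv, index=["lower", "upper"]).T

    def bootstrap(self, **overrides) -> inference.BootstrapResult:
        spec = replace(self.spec, **overrides) if overrides else self.spec
        return inference.bootstrap_validate(self.model.data, self.model.config,
                                            spec)

    def predicted(self) -> pd.DataFrame:
        return self.model.predict(params=self.point.params)

    def summary(self) -> str:
        lines = ["pSTAT response model fit",
                 "=" * 48,
                 f"predictor:      {self.spec.predictor}",
                 f"n records:      {len(self.model.data)}",
                 f"relative MAE:   {self.loss:.4f}",
                 "-" * 48,
                 f"{'parameter':<20}{'estimate':>12}  90% interval"]
        iv = self.chains.interval(0.9) if self.chains is not None else {}
        for p, v in self.point.params.items():
            if p in iv:
                lo, hi = iv[p]
                lines.append(f"{p:<20}{v:>12.4g}  [{lo:.4g}, {hi:.4g}]")
            else:
                lines.append(f"{p:<20}{v:>12.4g}")
        if self.chains is not None:
            rhat = ", ".join(f"{p}={r:.3f}" for p, r in
                             zip(self.chains.param_names, self.chains.rhat))
            lines += ["-" * 48,
                      f"split-Rhat:     {rhat}",
                      f"acceptance:     {np.mean(self.chains.acceptance):.2f}"]
        return "\n".join(lines)
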