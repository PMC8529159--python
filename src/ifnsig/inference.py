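"""Parameter estimation against response panels.

The loss is the relative mean absolute error over matched records,
mean(|pred - obs| / obs), matching how fit quality is quoted as a percentage.
Point estimation is multi-start bounded local optimization in log-parameter
space; posterior sampling uses an adaptive Metropolis random walk in the same
space with log-uniform priors over the bounds.  Wide marginals are expected:
models of this kind are "sloppy" and the data constrain only a few stiff
parameter combinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import population

KEYS = ["ligand", "dose_pM", "time_min"]


class ZeroObservationWarning(UserWarning):
    """Zero-valued observations carry no relative error and are dropped."""


# --- free-parameter registry ------------------------------------------------

def _set_receptor_median(cfg, v):
    pop = replace(cfg.population, median_r1=v, median_r2=v)
    return replace(cfg, population=pop)


def _set_kp(cfg, v):
    from .params import PStatParams
    pp = PStatParams(cfg.pp.ST, v)
    kin = {n: replace(k, kp_plus=k.kp_minus / v) for n, k in cfg.kinetics.items()}
    return replace(cfg, pp=pp, kinetics=kin)


def _set_st(cfg, v):
    from .params import PStatParams
    return replace(cfg, pp=PStatParams(v, cfg.pp.Kp))


def _set_mfi_scale(cfg, v):
    return replace(cfg, population=replace(cfg.population, mfi_scale=v))


def _ligand_rate_setter(rate_name):
    def setter(cfg, v, ligand):
        kin = dict(cfg.kinetics)
        kin[ligand] = replace(kin[ligand], **{rate_name: v})
        return replace(cfg, kinetics=kin)
    return setter


SETTERS = {
    "receptor_median": _set_receptor_median,
    "kp": _set_kp,
    "st": _set_st,
    "mfi_scale": _set_mfi_scale,
}
LIGAND_RATES = {"k_int_induced", "k_rec1", "k_rec2", "k_socs", "kp_minus"}


def apply_free_params(config: population.ModelConfig,
                      names: list[str], values) -> population.ModelConfig:
    """Return a config with the named free parameters set.

    Plain names come from the registry (``receptor_median``, ``kp``, ``st``,
    ``mfi_scale``); ligand-specific kinetic rates use ``rate:ligand`` syntax,
    e.g. ``k_int_induced:IFNb``.
    """
    cfg = config
    for name, v in zip(names, values):
        if ":" in name:
            rate, ligand = name.split(":", 1)
            if rate not in LIGAND_RATES:
                raise KeyError(f"unknown ligand rate {rate!r}")
            cfg = _ligand_rate_setter(rate)(cfg, float(v), ligand)
        else:
            try:
                cfg = SETTERS[name](cfg, float(v))
            except KeyError:
                raise KeyError(f"unknown free parameter {name!r}") from None
    return cfg


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how."""

    free: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    predictor: str = "equilibrium"
    n_starts: int = 5
    chains: int = 4
    steps: int = 5000
    burn_in: int = 1000
    seed: int = 0
    train_fraction: float = 0.8
    n_batches: int = 5
    noise_log_sd: float = 0.2

    def __post_init__(self) -> None:
        for p in self.free:
            lo, hi = self.bounds[p]
            if not (0 < lo < hi and np.isfinite(hi)):
                raise ValueError(f"bounds for {p!r} must be finite and positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie in (0, 1)")


def loss_mae(predicted: pd.DataFrame, observed: pd.DataFrame) -> float:
    """Relative MAE between matched (ligand, dose, time) records.

    Zero-valued observations (e.g. the zero-dose control) carry no relative
    error and are excluded.
    """
    def value_col(df, preferred):
        for c in preferred:
            if c in df.columns:
                return c
        raise KeyError(f"no value column among {preferred} in {list(df.columns)}")

    oc = value_col(observed, ("obs", "mfi", "mean_mfi"))
    pc = value_col(predicted, ("pred", "mean_mfi", "mfi"))
    obs = observed[KEYS + [oc]].rename(columns={oc: "obs"})
    pred = predicted[KEYS + [pc]].rename(columns={pc: "pred"})
    merged = obs.merge(pred, on=KEYS, how="inner")
    if merged.empty:
        raise ValueError("no matching records between prediction and data")
    nz = merged["obs"] != 0
    if not nz.all():
        warnings.warn("excluding zero-valued observations from relative MAE",
                      ZeroObservationWarning)
    m = merged[nz]
    return float(np.mean(np.abs(m["pred"] - m["obs"]) / m["obs"]))


class PanelPredictor:
    """Predict a panel's mean MFI for a free-parameter vector.

    Evaluates the population model on the panel's (ligand, dose, time) grid;
    results are cached per parameter vector.
    """

    def __init__(self, panel: pd.DataFrame, config: population.ModelConfig,
                 spec: FitSpec):
        self.config = config
        self.spec = spec
        self.grid = panel[KEYS].drop_duplicates()
        self.doses = np.sort(self.grid["dose_pM"].unique())
        self.times = np.sort(self.grid["time_min"].unique())
        self.ligands = list(self.grid["ligand"].unique())
        self._cache: dict[tuple, pd.DataFrame] = {}

    def __call__(self, values) -> pd.DataFrame:
        key = tuple(np.round(np.asarray(values, dtype=float), 12))
        if key not in self._cache:
            cfg = apply_free_params(self.config, list(self.spec.free), values)
            mean = population.population_response(
                cfg, self.doses, self.times, ligands=self.ligands,
                seed=self.spec.seed, predictor=self.spec.predictor)
            if len(self._cache) > 128:
                self._cache.clear()
            self._cache[key] = mean.rename(columns={"mean_mfi": "pred"})
        return self._cache[key]


@dataclass
class PointFit:
    params: dict[str, float]
    loss: float
    starts: list[dict] = field(default_factory=list)


def fit_point(panel: pd.DataFrame, config: population.ModelConfig,
              spec: FitSpec) -> PointFit:
    """Multi-start bounded minimisation of the relative MAE in log space."""
    obs = _observed_means(panel)
    predictor = PanelPredictor(panel, config, spec)
    lo = np.log([spec.bounds[p][0] for p in spec.free])
    hi = np.log([spec.bounds[p][1] for p in spec.free])
    rng = np.random.default_rng(spec.seed)

    def objective(logv):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ZeroObservationWarning)
            return loss_mae(predictor(np.exp(logv)), obs)

    best, starts = None, []
    x0s = [0.5 * (lo + hi)] + [rng.uniform(lo, hi) for _ in range(spec.n_starts - 1)]
    for x0 in x0s:
        try:
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-10,
                                    "maxiter": 2000})
            res.x = np.clip(res.x, lo, hi)
            starts.append({"x0": np.exp(x0).tolist(), "loss": float(res.fun)})
            if best is None or res.fun < best.fun:
                best = res
        except Exception as err:
            starts.append({"x0": np.exp(x0).tolist(), "error": str(err)})
    if best is None:
        raise RuntimeError(f"all optimisation starts failed: {starts}")
    values = np.exp(best.x)
    return PointFit(dict(zip(spec.free, map(float, values))),
                    float(best.fun), starts)


def _observed_means(panel: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged observations (keeps zero-dose rows)."""
    col = "mfi" if "mfi" in panel.columns else "mean_mfi"
    return (panel.groupby(KEYS, as_index=False)[col].mean()
            .rename(columns={col: "obs"}))


# --- MCMC -------------------------------------------------------------------

@dataclass
class McmcResult:
    """Posterior samples (post burn-in) and diagnostics."""

    samples: np.ndarray          # (chains, kept_steps, n_params)
    param_names: tuple[str, ...]
    acceptance: np.ndarray
    rhat: np.ndarray

    def flat(self) -> np.ndarray:
        return self.samples.reshape(-1, self.samples.shape[-1])

    def interval(self, level: float = 0.9) -> dict[str, tuple[float, float]]:
        q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
        flat = self.flat()
        return {p: tuple(np.percentile(flat[:, i], q))
                for i, p in enumerate(self.param_names)}

    def median(self) -> dict[str, float]:
        flat = self.flat()
        return {p: float(np.median(flat[:, i]))
                for i, p in enumerate(self.param_names)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in range(self.samples.shape[0]):
            df = pd.DataFrame(self.samples[c], columns=list(self.param_names))
            df.insert(0, "chain", c)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def _log_likelihood(pred: pd.DataFrame, obs: pd.DataFrame,
                    log_sd: float) -> float:
    merged = obs.merge(pred[KEYS + ["pred"]], on=KEYS, how="inner")
    m = merged[(merged["obs"] > 0) & (merged["pred"] > 0)]
    if m.empty or len(m) < len(merged[merged["obs"] > 0]):
        return -np.inf
    r = np.log(m["pred"].to_numpy() / m["obs"].to_numpy())
    return float(-0.5 * np.sum((r / log_sd) ** 2))


def split_rhat(samples: np.ndarray) -> np.ndarray:
    """Split-chain potential-scale-reduction statistic per parameter."""
    c, n, p = samples.shape
    half = n // 2
    parts = samples[:, :half * 2].reshape(c * 2, half, p)
    means = parts.mean(axis=1)
    w = parts.var(axis=1, ddof=1).mean(axis=0)
    b = half * means.var(axis=0, ddof=1)
    var = (half - 1) / half * w + b / half
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var / w)


def fit_mcmc(panel: pd.DataFrame, config: population.ModelConfig,
             spec: FitSpec) -> McmcResult:
    """Adaptive Metropolis in log-parameter space with log-uniform priors."""
    obs = _observed_means(panel)
    predictor = PanelPredictor(panel, config, spec)
    lo = np.log([spec.bounds[p][0] for p in spec.free])
    hi = np.log([spec.bounds[p][1] for p in spec.free])
    ndim = len(spec.free)

    def logpost(logv):
        if np.any(logv < lo) or np.any(logv > hi):
            return -np.inf
        return _log_likelihood(predictor(np.exp(logv)), obs, spec.noise_log_sd)

    rng = np.random.default_rng(spec.seed)
    kept = spec.steps - spec.burn_in
    samples = np.empty((spec.chains, kept, ndim))
    acc = np.zeros(spec.chains)
    for c in range(spec.chains):
        x, lp = None, -np.inf
        for _ in range(100):
            cand = rng.uniform(lo, hi)
            lp = logpost(cand)
            if np.isfinite(lp):
                x = cand
                break
        if x is None:
            raise RuntimeError("no finite-likelihood start found in prior")
        step = 0.1 * (hi - lo)
        accepted = 0
        for i in range(spec.steps):
            prop = x + step * rng.standard_normal(ndim)
            lp_prop = logpost(prop)
            if np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepted += 1
            # Robbins-Monro scale adaptation toward ~30% acceptance,
            # frozen after burn-in to keep the kept chain Markovian.
            if i < spec.burn_in:
                rate = accepted / (i + 1)
                step *= np.exp(0.01 * (rate - 0.3))
            if i >= spec.burn_in:
                samples[c, i - spec.burn_in] = x
        acc[c] = accepted / spec.steps
    return McmcResult(np.exp(samples), tuple(spec.free), acc,
                      split_rhat(samples))


# --- bootstrap validation ---------------------------------------------------

@dataclass
class BootstrapResult:
    train_losses: list[float]
    test_losses: list[float]

    @property
    def dispersion(self) -> float:
        t = np.asarray(self.test_losses)
        return float(t.max() / max(t.min(), 1e-300))


def bootstrap_validate(panel: pd.DataFrame, config: population.ModelConfig,
                       spec: FitSpec) -> BootstrapResult:
    """Stratified train/test splits: fit on train, score on held-out records.

    Replicates are split within each (ligand, dose, time) stratum so every
    batch keeps full dose and time coverage.
    """
    if panel.groupby(KEYS).size().min() < 2:
        raise ValueError("need >= 2 replicates per stratum for the split")
    rng = np.random.default_rng(spec.seed)
    train_losses, test_losses = [], []
    for b in range(spec.n_batches):
        mask = np.zeros(len(panel), dtype=bool)
        for _, idx in panel.groupby(KEYS).indices.items():
            idx = np.asarray(idx)
            n_train = max(1, int(round(spec.train_fraction * idx.size)))
            if n_train == idx.size:
                n_train = idx.size - 1
            take = rng.permutation(idx.size)[:n_train]
            mask[idx[take]] = True
        train, test = panel[mask], panel[~mask]
        sub = replace(spec, seed=spec.seed + 1000 + b, n_starts=2)
        fit = fit_point(train, config, sub)
        predictor = PanelPredictor(panel, config, sub)
        pred = predictor([fit.params[p] for p in sub.free])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ZeroObservationWarning)
            train_losses.append(loss_mae(pred, _observed_means(train)))
            test_losses.append(loss_mae(pred, _observed_means(test)))
    return BootstrapResult(train_losses, test_losses)
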