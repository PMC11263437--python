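"""Repeated cross-validation, Savitzky-Golay grid search and the three
breeding scenarios.

Prediction ability is the Pearson correlation between predicted and
observed genotype values.  Cross-validation assigns genotypes to k
folds at random (fold sizes differ by at most one) and is replicated;
when a scenario uses column scaling, the scaling statistics are refit
on the training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import SpectraMatrix
from .errors import ConfigError
from .predictors import fit_plsr, fit_rrblup
from .preprocess import (ColumnScaler, FESConfig, SGParams, apply_fes)


@dataclass(frozen=True)
class ModelSpec:
    """Which prediction model to use."""

    kind: str = "rrblup"  # rrblup | plsr
    n_components: int = 12
    lam: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("rrblup", "plsr"):
            raise ConfigError("model kind must be 'rrblup' or 'plsr'")


def fit_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    if spec.kind == "rrblup":
        return fit_rrblup(X, y, lam=spec.lam)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_plsr(X, y, n_components=spec.n_components)


@dataclass
class CVConfig:
    k: int = 5
    n_replicates: int = 1000
    seed: int = 0
    ability_mode: str = "per_fold_mean"  # or "pooled"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError("k must be >= 2")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.ability_mode not in ("per_fold_mean", "pooled"):
            raise ConfigError("unknown ability_mode")


@dataclass
class CVResult:
    abilities: np.ndarray
    config: CVConfig
    model: ModelSpec

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.abilities))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.abilities, ddof=1)) \
            if len(self.abilities) > 1 else 0.0


def pearson_ability(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation; NaN (with a warning) if either side is
    constant."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if np.std(pred) < 1e-14 or np.std(obs) < 1e-14:
        warnings.warn("zero-variance vector in ability computation")
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1])


def cv_prediction_ability(X: np.ndarray, y: np.ndarray, model: ModelSpec,
                          cv: CVConfig, scale_within_folds: bool = False
                          ) -> CVResult:
    """Repeated k-fold CV ability of one model on genotype-level data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < cv.k:
        raise ConfigError(f"need at least k={cv.k} genotypes, got {n}")
    if X.shape[0] != n:
        raise ConfigError("X rows and y length differ")
    rng = np.random.default_rng(cv.seed)
    abilities = np.empty(cv.n_replicates)
    for rep in range(cv.n_replicates):
        perm = rng.permutation(n)
        folds = np.array_split(perm, cv.k)
        fold_r, pooled_pred, pooled_obs = [], [], []
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            Xtr, Xte = X[mask], X[fold]
            if scale_within_folds:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scaler = ColumnScaler().fit(Xtr)
                    Xtr, Xte = scaler.transform(X[mask]), \
                        scaler.transform(X[fold])
            m = fit_model(model, Xtr, y[mask])
            pred = m.predict(Xte)
            if cv.ability_mode == "per_fold_mean":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = pearson_ability(pred, y[fold])
                if np.isfinite(r):
                    fold_r.append(r)
            else:
                pooled_pred.append(pred)
                pooled_obs.append(y[fold])
        if cv.ability_mode == "per_fold_mean":
            abilities[rep] = np.mean(fold_r) if fold_r else np.nan
        else:
            abilities[rep] = pearson_ability(np.concatenate(pooled_pred),
                                             np.concatenate(pooled_obs))
    if np.isnan(abilities).any():
        warnings.warn("some CV replicates had undefined ability "
                      "(zero-variance folds); excluded from the mean")
    return CVResult(abilities, cv, model)


@dataclass
class GridSearchResult:
    table: pd.DataFrame           # one row per SG combination
    best: SGParams
    highest_ability: float
    lowest_ability: float

    def to_json(self) -> str:
        import json
        return json.dumps({
            "best": self.best.as_tuple(),
            "highest_ability": self.highest_ability,
            "lowest_ability": self.lowest_ability,
            "table": self.table.to_dict(orient="records")},
            sort_keys=True)


def select_best_combination(table: pd.DataFrame) -> SGParams:
    """Max mean ability; exact ties resolved by parsimony: smallest
    (derivative order, polynomial order, window size), in that
    priority."""
    best_mean = table["mean_ability"].max()
    tied = table[table["mean_ability"] == best_mean]
    tied = tied.sort_values(["derivative_order", "polynomial_order",
                             "window_size"])
    row = tied.iloc[0]
    return SGParams(int(row["polynomial_order"]),
                    int(row["derivative_order"]), int(row["window_size"]))


def grid_search_sg(plot_spectra: SpectraMatrix, records: pd.DataFrame,
                   trait: str, fes: FESConfig, grid: Sequence[SGParams],
                   model: ModelSpec, cv: CVConfig, variant: str = "series"
                   ) -> GridSearchResult:
    """Tune the Savitzky-Golay triple by repeated-CV ability.

    The full FES pipeline (filter -> aggregate -> scale-in-CV) is rerun
    per combination; genotype BLUE matrices are cached per combination
    so repeated searches on the same data reuse the mixed-model fits.
    """
    if not fes.use_sg:
        raise ConfigError("grid search requires a filtering FES (use_sg)")
    if not grid:
        raise ConfigError("empty parameter grid")
    cache: dict = {}
    rows = []
    for sgp in grid:
        data = apply_fes(plot_spectra, records, trait, fes, sg=sgp,
                         variant=variant, apply_scaling=False,
                         blue_cache=cache)
        res = cv_prediction_ability(data.X, data.y, model, cv,
                                    scale_within_folds=fes.use_scaling)
        rows.append({"polynomial_order": sgp.polynomial_order,
                     "derivative_order": sgp.derivative_order,
                     "window_size": sgp.window_size,
                     "mean_ability": res.mean, "sd_ability": res.sd})
    table = pd.DataFrame(rows)
    best = select_best_combination(table)
    return GridSearchResult(table, best,
                            float(table["mean_ability"].max()),
                            float(table["mean_ability"].min()))


@dataclass
class ScenarioResult:
    scenario_id: int
    units: list = field(default_factory=list)  # dicts with name + ability

    @property
    def abilities(self) -> np.ndarray:
        return np.array([u["ability"] for u in self.units], dtype=float)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.abilities)) if self.units else np.nan

    @property
    def sd(self) -> float:
        a = self.abilities
        return float(np.nanstd(a, ddof=1)) if len(a) > 1 else 0.0


def _env_subset(plot_spectra: SpectraMatrix, records: pd.DataFrame,
                env: str) -> tuple[SpectraMatrix, pd.DataFrame]:
    sub = records[records["environment"] == env].reset_index(drop=True)
    idx = {r: i for i, r in enumerate(plot_spectra.row_ids)}
    rows = [idx[p] for p in sub["plot_id"]]
    return plot_spectra.select_rows(rows), sub


def scenario1_within_env(plot_spectra: SpectraMatrix, records: pd.DataFrame,
                         trait: str, fes: FESConfig,
                         sg: Optional[SGParams], model: ModelSpec,
                         cv: CVConfig,
                         environments: Optional[Sequence[str]] = None
                         ) -> ScenarioResult:
    """Predict new genotypes from spectra obtained in the training
    environment: repeated genotype-fold CV within each environment."""
    envs = (list(environments) if environments is not None
            else sorted(records["environment"].unique()))
    result = ScenarioResult(1)
    for env in envs:
        spec_e, rec_e = _env_subset(plot_spectra, records, env)
        data = apply_fes(spec_e, rec_e, trait, fes, sg=sg,
                         variant="within_environment", apply_scaling=False)
        res = cv_prediction_ability(data.X, data.y, model, cv,
                                    scale_within_folds=fes.use_scaling)
        result.units.append({"name": env, "ability": res.mean,
                             "sd": res.sd, "n_genotypes": len(data.y)})
    return result


def _genotype_level(plot_spectra, records, trait, fes, sg, env):
    spec_e, rec_e = _env_subset(plot_spectra, records, env)
    return apply_fes(spec_e, rec_e, trait, fes, sg=sg,
                     variant="within_environment", apply_scaling=False)


def scenario2_cross_env(plot_spectra: SpectraMatrix, records: pd.DataFrame,
                        trait: str, fes: FESConfig,
                        sg: Optional[SGParams], model: ModelSpec,
                        train_env: Optional[str] = None,
                        env_pairs: Optional[Sequence[tuple]] = None
                        ) -> ScenarioResult:
    """Train in one environment, predict the same genotypes from their
    spectra in another environment: one ability per ordered pair."""
    envs = sorted(records["environment"].unique())
    if env_pairs is None:
        trains = [train_env] if train_env is not None else envs
        env_pairs = [(a, b) for a in trains for b in envs if b != a]
    data_cache = {}

    def level(env):
        if env not in data_cache:
            data_cache[env] = _genotype_level(plot_spectra, records, trait,
                                              fes, sg, env)
        return data_cache[env]

    result = ScenarioResult(2)
    for a, b in env_pairs:
        da, db = level(a), level(b)
        shared = sorted(set(da.genotypes) & set(db.genotypes))
        if len(shared) < 3:
            raise ConfigError(
                f"environments {a} and {b} share fewer than 3 genotypes")
        # reconcile wavelength grids (dropped-wavelength intersection)
        common_wl = np.intersect1d(da.wavelengths, db.wavelengths)
        ka = np.isin(da.wavelengths, common_wl)
        kb = np.isin(db.wavelengths, common_wl)
        Xa, Xb = da.X[:, ka], db.X[:, kb]
        ib = {g: i for i, g in enumerate(db.genotypes)}
        if fes.use_scaling:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scaler = ColumnScaler().fit(Xa)
                Xb_s = scaler.transform(Xb)
                Xa_s = scaler.transform(Xa)
        else:
            Xa_s, Xb_s = Xa, Xb
        m = fit_model(model, Xa_s, da.y)
        pred = m.predict(Xb_s[[ib[g] for g in shared]])
        obs = db.y[[ib[g] for g in shared]]
        result.units.append({"name": f"{a}->{b}",
                             "ability": pearson_ability(pred, obs),
                             "n_genotypes": len(shared)})
    return result


def scenario3_series(train_X: SpectraMatrix, train_y: pd.Series,
                     central_X: SpectraMatrix, series_y: pd.Series,
                     model: ModelSpec, use_scaling: bool = True
                     ) -> ScenarioResult:
    """Train on series-level genotype BLUEs; predict new genotypes'
    phenomic estimated performance (PEP) from central-environment
    spectra and correlate with their series trait BLUEs."""
    overlap = set(train_X.row_ids) & set(central_X.row_ids)
    if overlap:
        warnings.warn(f"{len(overlap)} genotypes appear in both training "
                      "and prediction sets")
    missing = [g for g in central_X.row_ids if g not in series_y.index]
    if missing:
        raise ConfigError(
            f"series trait BLUEs missing for genotypes: {missing[:5]}")
    train_ids = [g for g in train_X.row_ids if g in train_y.index]
    if len(train_ids) < 3:
        raise ConfigError("fewer than 3 training genotypes with trait data")
    common_wl = np.intersect1d(train_X.wavelengths, central_X.wavelengths)
    ktr = np.isin(train_X.wavelengths, common_wl)
    kce = np.isin(central_X.wavelengths, common_wl)
    itr = {g: i for i, g in enumerate(train_X.row_ids)}
    Xtr = train_X.values[[itr[g] for g in train_ids]][:, ktr]
    ytr = train_y.loc[train_ids].to_numpy(dtype=float)
    Xce = central_X.values[:, kce]
    if use_scaling:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaler = ColumnScaler().fit(Xtr)
            Xce_s = scaler.transform(Xce)
            Xtr_s = scaler.transform(Xtr)
    else:
        Xtr_s, Xce_s = Xtr, Xce
    m = fit_model(model, Xtr_s, ytr)
    pep = m.predict(Xce_s)
    obs = series_y.loc[list(central_X.row_ids)].to_numpy(dtype=float)
    result = ScenarioResult(3)
    result.units.append({"name": "central->series",
                         "ability": pearson_ability(pep, obs),
                         "n_genotypes": len(obs)})
    return result
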