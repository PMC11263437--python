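"""Spectral preprocessing and the eight feature-engineering scenarios.

Pipeline order is fixed: optional Savitzky-Golay filtering at plot
level, then aggregation to genotype level (arithmetic mean or
mixed-model BLUE), then optional column centering/scaling.  Scaling can
be deferred so cross-validation refits the column statistics on the
training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .containers import SpectraMatrix
from .errors import ConfigError, DegenerateModelError
from .trial_models import spectra_blues, estimate_blues

#: default tuning grid levels
SG_POLY_ORDERS = (2, 3, 4)
SG_DERIV_ORDERS = (1, 2)
SG_WINDOW_SIZES = (29, 39, 49, 59, 69, 79, 89)


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay parameter triple (window w, polynomial p, derivative d)."""

    polynomial_order: int = 2
    derivative_order: int = 1
    window_size: int = 29

    def __post_init__(self) -> None:
        if self.window_size % 2 == 0:
            raise ConfigError("window_size must be odd")
        if self.derivative_order > self.polynomial_order:
            raise ConfigError("derivative_order must be <= polynomial_order")
        if self.polynomial_order >= self.window_size:
            raise ConfigError("polynomial_order must be < window_size")
        if self.derivative_order < 1:
            raise ConfigError("derivative_order must be >= 1")

    @property
    def half_window(self) -> int:
        return (self.window_size - 1) // 2

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.polynomial_order, self.derivative_order,
                self.window_size)


def default_sg_grid() -> list[SGParams]:
    """The full 42-combination tuning grid."""
    return [SGParams(p, d, w)
            for p in SG_POLY_ORDERS
            for d in SG_DERIV_ORDERS
            for w in SG_WINDOW_SIZES]


# FES id -> (use_sg, aggregation, use_scaling); trait aggregation follows
# the NIRS aggregation.  Ids 1-4 are unfiltered, 5-8 Savitzky-Golay
# filtered; within each half: mean / mean+scale / BLUE / BLUE+scale.
_FES_TABLE = {
    1: (False, "mean", False),
    2: (False, "mean", True),
    3: (False, "blue", False),
    4: (False, "blue", True),
    5: (True, "mean", False),
    6: (True, "mean", True),
    7: (True, "blue", False),
    8: (True, "blue", True),
}


@dataclass(frozen=True)
class FESConfig:
    """One feature-engineering scenario."""

    fes_id: int

    def __post_init__(self) -> None:
        if self.fes_id not in _FES_TABLE:
            raise ConfigError("fes_id must be in 1..8")

    @property
    def use_sg(self) -> bool:
        return _FES_TABLE[self.fes_id][0]

    @property
    def nirs_aggregation(self) -> str:
        return _FES_TABLE[self.fes_id][1]

    @property
    def trait_aggregation(self) -> str:
        return _FES_TABLE[self.fes_id][1]

    @property
    def use_scaling(self) -> bool:
        return _FES_TABLE[self.fes_id][2]


def savitzky_golay(spectra: SpectraMatrix, params: SGParams) -> SpectraMatrix:
    """Moving-window local polynomial derivative filter.

    Each retained point is the ``d``-th derivative (per nm) of the
    degree-``p`` least-squares fit in the centred window; the grid is
    trimmed by ``(w-1)/2`` points at each edge.
    """
    n_wl = spectra.n_wavelengths
    if params.window_size > n_wl:
        raise ConfigError(
            f"window_size {params.window_size} exceeds grid length {n_wl}")
    step = spectra.step  # also validates uniformity
    filt = savgol_filter(spectra.values, params.window_size,
                         params.polynomial_order,
                         deriv=params.derivative_order, delta=step,
                         axis=1, mode="interp")
    h = params.half_window
    return SpectraMatrix(filt[:, h:n_wl - h], list(spectra.row_ids),
                         spectra.wavelengths[h:n_wl - h])


class ColumnScaler:
    """Center/scale columns with statistics learnt on a training matrix.

    Zero-variance columns (training sd below ``tol``) are dropped with a
    warning; the same columns are dropped from transformed matrices.
    """

    def __init__(self, tol: float = 1e-12):
        self.tol = tol
        self.mean_: Optional[np.ndarray] = None
        self.sd_: Optional[np.ndarray] = None
        self.keep_: Optional[np.ndarray] = None

    def fit(self, matrix: np.ndarray) -> "ColumnScaler":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[0] < 2:
            raise ConfigError("scaling needs at least 2 rows")
        self.mean_ = matrix.mean(axis=0)
        self.sd_ = matrix.std(axis=0, ddof=1)
        self.keep_ = self.sd_ > self.tol
        if not self.keep_.any():
            raise DegenerateModelError("all columns have zero variance")
        if not self.keep_.all():
            warnings.warn(f"dropped {int((~self.keep_).sum())} "
                          "zero-variance column(s) during scaling")
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ConfigError("scaler not fitted")
        matrix = np.asarray(matrix, dtype=float)
        out = (matrix[:, self.keep_] - self.mean_[self.keep_]) \
            / self.sd_[self.keep_]
        return out

    def fit_transform(self, matrix: np.ndarray) -> np.ndarray:
        return self.fit(matrix).transform(matrix)


def scale_columns(matrix: np.ndarray) -> np.ndarray:
    """Center and scale every column (n-1 denominator); zero-variance
    columns are dropped with a warning."""
    return ColumnScaler().fit_transform(matrix)


def average_technical_replicates(spectra: SpectraMatrix) -> SpectraMatrix:
    """One row per plot id: arithmetic mean of its measurement replicates."""
    ids = np.asarray(spectra.row_ids, dtype=object)
    uniq, inv = np.unique(ids, return_inverse=True)
    counts = np.bincount(inv)
    if (counts < 1).any():
        raise ConfigError("plot with no replicate rows")
    sums = np.zeros((len(uniq), spectra.n_wavelengths))
    np.add.at(sums, inv, spectra.values)
    means = sums / counts[:, None]
    # keep first-appearance order of plots
    order = np.argsort([np.flatnonzero(inv == i)[0] for i in range(len(uniq))])
    return SpectraMatrix(means[order], [uniq[i] for i in order],
                         spectra.wavelengths.copy())


def genotype_mean(spectra: SpectraMatrix, genotype_map: dict
                  ) -> SpectraMatrix:
    """Genotype-level matrix: arithmetic mean over all plots of each
    genotype (across environments)."""
    unmapped = [r for r in spectra.row_ids if r not in genotype_map]
    if unmapped:
        raise ConfigError(f"rows without genotype mapping: {unmapped[:5]}")
    genos = np.asarray([genotype_map[r] for r in spectra.row_ids],
                       dtype=object)
    uniq, inv = np.unique(genos, return_inverse=True)
    sums = np.zeros((len(uniq), spectra.n_wavelengths))
    np.add.at(sums, inv, spectra.values)
    means = sums / np.bincount(inv)[:, None]
    return SpectraMatrix(means, list(uniq), spectra.wavelengths.copy())


@dataclass
class FESData:
    """Aligned genotype-level features and trait produced by a FES."""

    X: np.ndarray
    y: np.ndarray
    genotypes: list
    wavelengths: np.ndarray
    fes: FESConfig
    sg: Optional[SGParams]
    scaled: bool
    dropped_wavelengths: list


def apply_fes(plot_spectra: SpectraMatrix, records: pd.DataFrame,
              trait: str, fes: FESConfig, sg: Optional[SGParams] = None,
              variant: str = "series", apply_scaling: bool = True,
              blue_cache: Optional[dict] = None) -> FESData:
    """Run one feature-engineering scenario end to end.

    Order: [optional SG at plot level] -> [aggregate to genotype level,
    mean or BLUE] -> [optional scaling].  The trait is aggregated per
    the scenario (mean or BLUE, never scaled).  Set
    ``apply_scaling=False`` to defer scaling to cross-validation (the
    column statistics are then refit per training fold).

    ``blue_cache`` memoises genotype BLUE matrices by SG parameters so a
    tuning grid does not refit identical mixed models.
    """
    if fes.use_sg and sg is None:
        raise ConfigError(f"FES {fes.fes_id} requires SGParams")
    work = plot_spectra
    if fes.use_sg:
        work = savitzky_golay(work, sg)

    dropped: list = []
    if fes.nirs_aggregation == "mean":
        gmap = dict(zip(records["plot_id"], records["genotype"]))
        agg = genotype_mean(work, gmap)
    else:
        key = (None if sg is None else sg.as_tuple(), variant)
        if blue_cache is not None and key in blue_cache:
            agg, dropped = blue_cache[key]
        else:
            agg, dropped = spectra_blues(work, records, variant=variant)
            if blue_cache is not None:
                blue_cache[key] = (agg, dropped)

    if fes.trait_aggregation == "mean":
        y_series = records.groupby("genotype")[trait].mean()
    else:
        tb = estimate_blues(records, trait, variant=variant)
        y_series = tb.as_series()

    genotypes = [g for g in agg.row_ids if g in y_series.index]
    if len(genotypes) < len(agg.row_ids):
        warnings.warn("genotypes without trait values were dropped")
    gi = {g: i for i, g in enumerate(agg.row_ids)}
    X = agg.values[[gi[g] for g in genotypes]]
    y = y_series.loc[genotypes].to_numpy(dtype=float)

    scaled = False
    wavelengths = agg.wavelengths.copy()
    if fes.use_scaling and apply_scaling:
        scaler = ColumnScaler().fit(X)
        X = scaler.transform(X)
        wavelengths = wavelengths[scaler.keep_]
        scaled = True
    return FESData(X, y, list(genotypes), wavelengths, fes, sg,
                   scaled, list(dropped))
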