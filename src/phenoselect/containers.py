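"""Shared in-memory containers.

The plot table travels as a :class:`pandas.DataFrame` with the columns
``plot_id, genotype, environment, replicate, block`` plus one column per
trait.  Spectra travel as :class:`SpectraMatrix`: a dense row-per-sample
matrix over a strictly increasing wavelength grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

#: required plot-table columns
PLOT_COLUMNS = ("plot_id", "genotype", "environment", "replicate", "block")


def wavelength_columns(wavelengths) -> list[str]:
    """Column names of the CSV dialect: ``wl_<nm>`` (nm may be fractional)."""
    cols = []
    for w in np.asarray(wavelengths):
        if float(w) == int(w):
            cols.append(f"wl_{int(w)}")
        else:
            cols.append(f"wl_{float(w):g}")
    return cols


@dataclass
class SpectraMatrix:
    """Rows (plots, technical replicates, or genotypes) x wavelength grid."""

    values: np.ndarray
    row_ids: list
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("spectra values must be a 2-D matrix")
        if self.values.shape != (len(self.row_ids), len(self.wavelengths)):
            raise ConfigError(
                f"shape mismatch: values {self.values.shape}, "
                f"{len(self.row_ids)} row ids, "
                f"{len(self.wavelengths)} wavelengths"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ConfigError("wavelength grid must be strictly increasing")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    @property
    def step(self) -> float:
        """Grid step; raises if the grid is not uniform."""
        diffs = np.diff(self.wavelengths)
        if len(diffs) == 0:
            raise ConfigError("grid step undefined for a single wavelength")
        step = diffs[0]
        if not np.allclose(diffs, step, rtol=0, atol=1e-9 * max(abs(step), 1.0)):
            raise ConfigError("wavelength grid is not uniform")
        return float(step)

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(self.values.copy(), list(self.row_ids),
                             self.wavelengths.copy())

    def select_rows(self, idx) -> "SpectraMatrix":
        idx = np.asarray(idx)
        return SpectraMatrix(self.values[idx],
                             [self.row_ids[i] for i in idx],
                             self.wavelengths.copy())

    def select_wavelengths(self, mask) -> "SpectraMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            return SpectraMatrix(self.values[:, mask], list(self.row_ids),
                                 self.wavelengths[mask])
        return SpectraMatrix(self.values[:, mask], list(self.row_ids),
                             self.wavelengths[mask])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values,
                          columns=wavelength_columns(self.wavelengths))
        df.insert(0, "plot_id", list(self.row_ids))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, id_column: str = "plot_id"
                   ) -> "SpectraMatrix":
        wl_cols = [c for c in df.columns if c.startswith("wl_")]
        wavelengths = np.array([float(c[3:]) for c in wl_cols])
        return cls(df[wl_cols].to_numpy(dtype=float),
                   df[id_column].tolist(), wavelengths)


def validate_plot_table(records: pd.DataFrame) -> None:
    missing = [c for c in ("plot_id", "genotype", "environment")
               if c not in records.columns]
    if missing:
        raise ConfigError(f"plot table missing required columns: {missing}")
    if records["plot_id"].duplicated().any():
        dupes = records.loc[records["plot_id"].duplicated(), "plot_id"]
        raise ConfigError(f"duplicate plot_id values: {sorted(set(dupes))[:5]}")
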