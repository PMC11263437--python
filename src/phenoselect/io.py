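"""CSV / JSON file formats.

Dialect: UTF-8, comma separated, header row, '.' decimal.  Plot tables
carry ``plot_id, genotype, environment, replicate, block`` plus trait
columns; spectra tables carry ``plot_id`` plus ``wl_<nm>`` columns on a
strictly increasing uniform grid.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SpectraMatrix, validate_plot_table
from .errors import ConfigError


def read_plot_table(path) -> pd.DataFrame:
    """Read and validate a plot table CSV.

    Missing ``replicate`` / ``block`` columns are filled with a single
    implicit level (with a warning).
    """
    df = pd.read_csv(path)
    validate_plot_table(df)
    for col, label in (("replicate", "replicate"), ("block", "block")):
        if col not in df.columns:
            warnings.warn(f"no {label} column in {path}; assuming a single "
                          f"{label}")
            df[col] = 1
    df["plot_id"] = df["plot_id"].astype(str)
    df["genotype"] = df["genotype"].astype(str)
    df["environment"] = df["environment"].astype(str)
    return df


def write_plot_table(records: pd.DataFrame, path) -> None:
    validate_plot_table(records)
    records.to_csv(path, index=False)


def read_spectra_table(path) -> SpectraMatrix:
    """Read a spectra CSV; errors name offending columns / cells."""
    df = pd.read_csv(path)
    if "plot_id" not in df.columns:
        raise ConfigError(f"{path}: missing plot_id column")
    wl_cols = [c for c in df.columns if c.startswith("wl_")]
    if not wl_cols:
        raise ConfigError(f"{path}: no wl_<nm> columns found")
    wls = np.array([float(c[3:]) for c in wl_cols])
    diffs = np.diff(wls)
    if (diffs <= 0).any():
        bad = wl_cols[int(np.argmax(diffs <= 0)) + 1]
        raise ConfigError(f"{path}: wavelength columns not strictly "
                          f"increasing at {bad}")
    if len(diffs) and not np.allclose(diffs, diffs[0], rtol=0, atol=1e-9):
        bad = wl_cols[int(np.argmax(~np.isclose(diffs, diffs[0]))) + 1]
        raise ConfigError(f"{path}: non-uniform wavelength grid at {bad}")
    values = df[wl_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ConfigError(f"{path}: NaN at row {int(r)} "
                          f"(plot {df['plot_id'].iloc[int(r)]}), "
                          f"column {wl_cols[int(c)]}")
    return SpectraMatrix(values, df["plot_id"].astype(str).tolist(), wls)


def write_spectra_table(spectra: SpectraMatrix, path) -> None:
    spectra.to_frame().to_csv(path, index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default))


def _json_default(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")
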