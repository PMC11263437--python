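"""Synthetic multi-environment trials with NIR spectra.

Generates field-trial layouts (partially replicated, alpha-lattice or
single replicate), then simulates plot-level traits from the additive
mixed-model structure

    y_ijsh = mu + g_i + l_j + r_js + b_jsh + gl_ij + e_ijsh

and plot-level spectra as a smooth base curve plus genotype,
genotype-by-environment and noise contributions projected through a
band-limited loading basis.  The per-wavelength variance split between
genotype, GxE and noise is controlled exactly by ``(p_g, p_gl, p_e)``,
and a tunable fraction of the trait's genetic (and GxE) variance is made
linearly predictable from the genotype (GxE) spectral scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import SpectraMatrix
from .errors import ConfigError, InvalidDesignError

DEFAULT_GRID = np.arange(1300.0, 2301.0)  # nm, 1 nm steps

_TRAIT_KEYS = ("sigma2_g", "sigma2_l", "sigma2_r", "sigma2_b",
               "sigma2_gl", "sigma2_e")


@dataclass
class DesignConfig:
    """Layout request for one multi-environment trial."""

    n_genotypes: int
    environments: Sequence[str]
    design_kind: str = "p_rep"  # p_rep | alpha_lattice | single_rep
    rep_fraction: float = 0.2   # p_rep: fraction of genotypes duplicated
    n_reps: int = 2             # alpha_lattice: replicates per environment
    block_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ConfigError("n_genotypes must be >= 2")
        if self.block_size < 2:
            raise ConfigError("block_size must be >= 2")
        if self.design_kind not in ("p_rep", "alpha_lattice", "single_rep"):
            raise ConfigError(f"unknown design_kind {self.design_kind!r}")
        if not self.environments:
            raise ConfigError("at least one environment required")
        if self.design_kind == "p_rep" and not 0.0 <= self.rep_fraction <= 1.0:
            raise ConfigError("rep_fraction must be in [0, 1]")
        if self.design_kind == "alpha_lattice" and self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")


@dataclass
class VarianceConfig:
    """Variance structure of the simulated trait and spectra."""

    trait: dict = field(default_factory=lambda: {
        "sigma2_g": 0.15, "sigma2_l": 0.30, "sigma2_r": 0.02,
        "sigma2_b": 0.02, "sigma2_gl": 0.29, "sigma2_e": 0.20})
    p_g: float = 0.40
    p_gl: float = 0.50
    p_e: float = 0.10
    link_strength: float = 0.8
    mu: float = 6.5
    rank: int = 6            # number of smooth loading functions
    bump_width: Optional[float] = None  # nm; default derived from grid span
    env_offset_scale: float = 1.0
    spectral_amplitude: float = 0.05

    def __post_init__(self) -> None:
        for k in _TRAIT_KEYS:
            if k not in self.trait:
                raise ConfigError(f"trait variance {k} missing")
            if self.trait[k] < 0:
                raise ConfigError(f"trait variance {k} must be >= 0")
        for name, p in (("p_g", self.p_g), ("p_gl", self.p_gl),
                        ("p_e", self.p_e)):
            if p < 0:
                raise ConfigError(f"{name} must be >= 0")
        if abs(self.p_g + self.p_gl + self.p_e - 1.0) > 1e-12:
            raise ConfigError("p_g + p_gl + p_e must sum to 1")
        if not 0.0 <= self.link_strength <= 1.0:
            raise ConfigError("link_strength must be in [0, 1]")
        if self.rank < 1:
            raise ConfigError("rank must be >= 1")


@dataclass
class EffectSet:
    """Ground-truth effects returned by :func:`simulate_dataset`."""

    genotypes: list
    environments: list
    g_trait: np.ndarray          # (n_geno,) trait-unit genotype effects
    l_effects: np.ndarray        # (n_env,)
    r_effects: dict              # (env, rep) -> effect
    b_effects: dict              # (env, rep, block) -> effect
    gl_trait: np.ndarray         # (n_geno, n_env)
    residuals: np.ndarray        # (n_plots,)
    g_scores: np.ndarray         # (n_geno, rank) genotype spectral scores
    gl_scores: np.ndarray        # (n_geno, n_env, rank) GxE spectral scores
    loadings: np.ndarray         # (rank, n_wavelengths) smooth basis
    base_curve: np.ndarray       # (n_wavelengths,)
    env_offsets: np.ndarray      # (n_env, n_wavelengths)

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {"|".join(map(str, k)) if isinstance(k, tuple) else k:
                        conv(v) for k, v in x.items()}
            return x
        return json.dumps({k: conv(v) for k, v in asdict(self).items()})


def _blocks_for(n_plots: int, block_size: int) -> list[int]:
    """Block label per plot position; sizes differ by at most 1."""
    n_blocks = max(1, int(np.ceil(n_plots / block_size)))
    base, extra = divmod(n_plots, n_blocks)
    labels = []
    for b in range(n_blocks):
        labels.extend([b + 1] * (base + (1 if b < extra else 0)))
    return labels


def generate_design(config: DesignConfig) -> pd.DataFrame:
    """Lay out the plot table for one trial.

    Returns a data frame with ``plot_id, genotype, environment,
    replicate, block`` (no trait columns yet).
    """
    rng = np.random.default_rng(config.seed)
    genotypes = [f"G{i + 1:04d}" for i in range(config.n_genotypes)]
    rows = []
    for env in config.environments:
        if config.design_kind == "alpha_lattice":
            per_rep = config.n_genotypes
            if config.block_size > per_rep:
                raise InvalidDesignError(
                    f"block_size {config.block_size} exceeds plots per "
                    f"replicate ({per_rep})")
            for rep in range(1, config.n_reps + 1):
                order = rng.permutation(config.n_genotypes)
                blocks = _blocks_for(per_rep, config.block_size)
                for pos, gi in enumerate(order):
                    rows.append((env, rep, blocks[pos], genotypes[gi]))
        else:
            entries = list(range(config.n_genotypes))
            if config.design_kind == "p_rep":
                n_dup = int(round(config.rep_fraction * config.n_genotypes))
                shuffled = rng.permutation(config.n_genotypes)
                entries += list(shuffled[:n_dup])
            order = rng.permutation(len(entries))
            if config.block_size > len(entries):
                raise InvalidDesignError(
                    f"block_size {config.block_size} exceeds plots per "
                    f"replicate ({len(entries)})")
            blocks = _blocks_for(len(entries), config.block_size)
            for pos, k in enumerate(order):
                rows.append((env, 1, blocks[pos], genotypes[entries[k]]))
    df = pd.DataFrame(rows, columns=["environment", "replicate", "block",
                                     "genotype"])
    df["plot_id"] = [
        f"{e}_r{r}_p{i + 1:04d}"
        for i, (e, r) in enumerate(zip(df["environment"], df["replicate"]))
    ]
    return df[["plot_id", "genotype", "environment", "replicate", "block"]]


def _loading_basis(grid: np.ndarray, rank: int,
                   bump_width: Optional[float]) -> np.ndarray:
    """Smooth band-limited loadings: Gaussian bumps spread over the grid."""
    span = grid[-1] - grid[0]
    centers = grid[0] + span * (np.arange(rank) + 0.5) / rank
    width = bump_width if bump_width is not None else 0.9 * span / rank
    return np.exp(-0.5 * ((grid[None, :] - centers[:, None]) / width) ** 2)


def simulate_dataset(design: pd.DataFrame, var_config: VarianceConfig,
                     wavelength_grid: Optional[np.ndarray] = None,
                     seed: int = 0, trait_name: str = "trait",
                     ) -> tuple[SpectraMatrix, pd.DataFrame, EffectSet]:
    """Simulate plot spectra and trait values on a given design.

    Returns ``(plot_spectra, plot_table_with_trait, truth)``.
    """
    grid = (DEFAULT_GRID if wavelength_grid is None
            else np.asarray(wavelength_grid, dtype=float))
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise ConfigError("wavelength grid must be strictly increasing")
    vc = var_config
    rng = np.random.default_rng(seed)

    genotypes = sorted(design["genotype"].unique())
    environments = sorted(design["environment"].unique())
    n_g, n_e, rank = len(genotypes), len(environments), vc.rank
    gi = {g: i for i, g in enumerate(genotypes)}
    ei = {e: j for j, e in enumerate(environments)}

    # spectral scores (unit variance) and trait-side effects
    g_scores = rng.standard_normal((n_g, rank))
    gl_scores = rng.standard_normal((n_g, n_e, rank))
    # random unit link weights: keeps the trait direction from lining up
    # with the dominant spectral principal component
    w = rng.standard_normal(rank)
    w /= np.linalg.norm(w)

    # the trait's GxE part links to the spectral GxE scores through
    # environment-specific weights (orthogonal across environments when
    # possible): an interaction learnt in one environment does not
    # transfer to another, mirroring how NIRS capture local GxE
    q_mat, _ = np.linalg.qr(rng.standard_normal((rank, rank)))
    w_env = np.stack([q_mat[:, j % rank] for j in range(n_e)])

    t = vc.trait
    lam = vc.link_strength
    g_trait = (np.sqrt(lam * t["sigma2_g"]) * (g_scores @ w)
               + np.sqrt((1 - lam) * t["sigma2_g"]) * rng.standard_normal(n_g))
    gl_link = np.einsum("ger,er->ge", gl_scores, w_env)
    gl_trait = (np.sqrt(lam * t["sigma2_gl"]) * gl_link
                + np.sqrt((1 - lam) * t["sigma2_gl"])
                * rng.standard_normal((n_g, n_e)))
    l_eff = np.sqrt(t["sigma2_l"]) * rng.standard_normal(n_e)

    rep_keys = sorted(set(zip(design["environment"], design["replicate"])))
    r_eff = {k: np.sqrt(t["sigma2_r"]) * rng.standard_normal()
             for k in rep_keys}
    blk_keys = sorted(set(zip(design["environment"], design["replicate"],
                              design["block"])))
    b_eff = {k: np.sqrt(t["sigma2_b"]) * rng.standard_normal()
             for k in blk_keys}

    n_plots = len(design)
    resid = np.sqrt(t["sigma2_e"]) * rng.standard_normal(n_plots)

    # spectral pieces
    load = _loading_basis(grid, rank, vc.bump_width)
    ssl = (load ** 2).sum(axis=0)            # per-wavelength basis power
    base = (0.45 + 0.25 * np.sin((grid - grid[0]) / (grid[-1] - grid[0] + 1)
                                 * 2.2 * np.pi)
            + 0.10 * (grid - grid[0]) / (grid[-1] - grid[0] + 1))
    broad = np.exp(-0.5 * ((grid - grid.mean())
                           / (0.35 * (grid[-1] - grid[0] + 1))) ** 2)
    env_draw = rng.standard_normal(n_e)
    env_offsets = (vc.env_offset_scale * vc.spectral_amplitude
                   * env_draw[:, None] * broad[None, :])

    amp = vc.spectral_amplitude
    spectra = np.empty((n_plots, len(grid)))
    trait = np.empty(n_plots)
    noise_sd = amp * np.sqrt(vc.p_e * ssl)
    for p, row in enumerate(design.itertuples(index=False)):
        i, j = gi[row.genotype], ei[row.environment]
        g_part = np.sqrt(vc.p_g) * (g_scores[i] @ load)
        gl_part = np.sqrt(vc.p_gl) * (gl_scores[i, j] @ load)
        eps = noise_sd * rng.standard_normal(len(grid))
        spectra[p] = base + env_offsets[j] + amp * (g_part + gl_part) + eps
        trait[p] = (vc.mu + g_trait[i] + l_eff[j]
                    + r_eff[(row.environment, row.replicate)]
                    + b_eff[(row.environment, row.replicate, row.block)]
                    + gl_trait[i, j] + resid[p])

    plot_spectra = SpectraMatrix(spectra, design["plot_id"].tolist(), grid)
    table = design.copy()
    table[trait_name] = trait
    truth = EffectSet(genotypes, environments, g_trait, l_eff, r_eff, b_eff,
                      gl_trait, resid, g_scores, gl_scores, load, base,
                      env_offsets)
    return plot_spectra, table, truth


def simulate_technical_replicates(spectra: SpectraMatrix, n_rep: int,
                                  noise_sd: float, seed: int = 0
                                  ) -> SpectraMatrix:
    """Expand each row into ``n_rep`` noisy measurement replicates.

    ``n_rep=1`` is a pass-through (no noise added).
    """
    if n_rep < 1:
        raise ConfigError("n_rep must be >= 1")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if n_rep == 1:
        return spectra.copy()
    rng = np.random.default_rng(seed)
    values = np.repeat(spectra.values, n_rep, axis=0)
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(values.shape)
    ids = [rid for rid in spectra.row_ids for _ in range(n_rep)]
    return SpectraMatrix(values, ids, spectra.wavelengths.copy())
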