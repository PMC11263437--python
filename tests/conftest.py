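import numpy as np
import pytest

from phenoselect import (DesignConfig, VarianceConfig, generate_design,
                         simulate_dataset)

SHORT_GRID = np.arange(1300.0, 2301.0, 10.0)  # 101 points, desk scale


def trait_variances(sigma2_g=0.5, sigma2_l=0.2, sigma2_r=0.02,
                    sigma2_b=0.02, sigma2_gl=0.3, sigma2_e=0.2):
    return {"sigma2_g": sigma2_g, "sigma2_l": sigma2_l,
            "sigma2_r": sigma2_r, "sigma2_b": sigma2_b,
            "sigma2_gl": sigma2_gl, "sigma2_e": sigma2_e}


@pytest.fixture(scope="session")
def small_trial():
    """60 genotypes x 2 environments, p-rep, linked spectra."""
    design = generate_design(DesignConfig(
        n_genotypes=60, environments=["E1", "E2"], design_kind="p_rep",
        rep_fraction=0.3, block_size=10, seed=11))
    var = VarianceConfig(trait=trait_variances(), p_g=0.5, p_gl=0.4,
                         p_e=0.1, link_strength=0.9)
    spectra, table, truth = simulate_dataset(design, var, SHORT_GRID,
                                             seed=12)
    return spectra, table, truth


@pytest.fixture(scope="session")
def single_env_trial():
    """120 genotypes, one environment, two alpha-lattice replicates."""
    design = generate_design(DesignConfig(
        n_genotypes=120, environments=["E1"], design_kind="alpha_lattice",
        n_reps=2, block_size=12, seed=21))
    var = VarianceConfig(trait=trait_variances(sigma2_l=0.0, sigma2_gl=0.0),
                         p_g=0.9, p_gl=0.0, p_e=0.1, link_strength=0.9)
    spectra, table, truth = simulate_dataset(design, var, SHORT_GRID,
                                             seed=22)
    return spectra, table, truth


@pytest.fixture(scope="session")
def noise_free_trial():
    """Perfectly linked, noise-free single-replicate dataset."""
    design = generate_design(DesignConfig(
        n_genotypes=150, environments=["E1"], design_kind="single_rep",
        block_size=10, seed=31))
    var = VarianceConfig(
        trait=trait_variances(sigma2_g=1.0, sigma2_l=0.0, sigma2_r=0.0,
                              sigma2_b=0.0, sigma2_gl=0.0, sigma2_e=0.0),
        p_g=1.0, p_gl=0.0, p_e=0.0, link_strength=1.0)
    spectra, table, truth = simulate_dataset(design, var, SHORT_GRID,
                                             seed=32)
    return spectra, table, truth
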