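import numpy as np
import pandas as pd
import pytest

import phenoselect as ps
from phenoselect import (CVConfig, FESConfig, ModelSpec, SGParams,
                         VarianceConfig, cv_prediction_ability,
                         grid_search_sg, pearson_ability,
                         scenario1_within_env, scenario2_cross_env,
                         scenario3_series, select_best_combination)
from phenoselect.errors import ConfigError

from conftest import SHORT_GRID, trait_variances


class TestPearsonAbility:
    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=30)
        obs = rng.normal(size=30)
        r0 = pearson_ability(pred, obs)
        r1 = pearson_ability(3.5 * pred + 2.0, obs)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(pearson_ability(np.ones(5), np.arange(5.0)))


class TestCVPredictionAbility:
    def test_perfect_link_high_ability(self, noise_free_trial):
        spectra, table, _ = noise_free_trial
        data = ps.apply_fes(spectra, table, "trait", FESConfig(1))
        res = cv_prediction_ability(data.X, data.y, ModelSpec("rrblup"),
                                    CVConfig(n_replicates=10, seed=1))
        assert res.mean > 0.99

    def test_null_link_centred_on_zero(self):
        # a single dataset carries chance correlation between y and the
        # low-rank feature span, so the null is checked as a grand mean
        # over independent datasets
        rng = np.random.default_rng(2)
        means = []
        for _ in range(6):
            X = rng.normal(size=(100, 40))
            y = rng.normal(size=100)
            res = cv_prediction_ability(X, y, ModelSpec("rrblup"),
                                        CVConfig(n_replicates=30, seed=3))
            means.append(res.mean)
        assert abs(np.mean(means)) < 0.08

    def test_same_seed_identical_vector(self, noise_free_trial):
        spectra, table, _ = noise_free_trial
        data = ps.apply_fes(spectra, table, "trait", FESConfig(1))
        cv = CVConfig(n_replicates=5, seed=7)
        r1 = cv_prediction_ability(data.X, data.y, ModelSpec(), cv)
        r2 = cv_prediction_ability(data.X, data.y, ModelSpec(), cv)
        np.testing.assert_array_equal(r1.abilities, r2.abilities)

    def test_fold_sizes_differ_by_at_most_one(self):
        # indirectly: n not divisible by k still works and uses all rows
        rng = np.random.default_rng(4)
        X = rng.normal(size=(23, 5))
        y = X[:, 0] + 0.1 * rng.normal(size=23)
        res = cv_prediction_ability(X, y, ModelSpec(),
                                    CVConfig(n_replicates=3, seed=5,
                                             ability_mode="pooled"))
        assert len(res.abilities) == 3

    def test_too_few_genotypes(self):
        with pytest.raises(ConfigError):
            cv_prediction_ability(np.ones((3, 2)), np.ones(3), ModelSpec(),
                                  CVConfig(k=5, n_replicates=1))

    def test_plsr_model_works(self, noise_free_trial):
        spectra, table, _ = noise_free_trial
        data = ps.apply_fes(spectra, table, "trait", FESConfig(1))
        res = cv_prediction_ability(data.X, data.y,
                                    ModelSpec("plsr", n_components=6),
                                    CVConfig(n_replicates=5, seed=8))
        assert res.mean > 0.95

    def test_monotone_in_link_strength(self):
        means = {0.0: [], 0.5: [], 1.0: []}
        for seed in range(6):
            design = ps.generate_design(ps.DesignConfig(
                80, ["E1"], "single_rep", block_size=10, seed=seed))
            for link in means:
                var = VarianceConfig(
                    trait=trait_variances(sigma2_g=1.0, sigma2_l=0,
                                          sigma2_r=0, sigma2_b=0,
                                          sigma2_gl=0, sigma2_e=0.3),
                    p_g=0.8, p_gl=0.0, p_e=0.2, link_strength=link)
                spectra, table, _ = ps.simulate_dataset(
                    design, var, SHORT_GRID, seed=100 + seed)
                data = ps.apply_fes(spectra, table, "trait", FESConfig(1))
                res = cv_prediction_ability(
                    data.X, data.y, ModelSpec(),
                    CVConfig(n_replicates=5, seed=seed))
                means[link].append(res.mean)
        m0, m5, m1 = (np.mean(means[k]) for k in (0.0, 0.5, 1.0))
        assert m0 < m5 < m1


class TestGridSearch:
    def test_all_tied_returns_parsimony_order(self):
        rows = [{"polynomial_order": p, "derivative_order": d,
                 "window_size": w, "mean_ability": 0.5, "sd_ability": 0.1}
                for p in (2, 3, 4) for d in (1, 2)
                for w in (29, 39, 49, 59, 69, 79, 89)]
        best = select_best_combination(pd.DataFrame(rows))
        assert best.as_tuple() == (2, 1, 29)

    def test_best_attains_max(self, small_trial):
        spectra, table, _ = small_trial
        grid = [SGParams(2, 1, 29), SGParams(2, 2, 29), SGParams(3, 1, 39)]
        res = grid_search_sg(spectra, table, "trait", FESConfig(6), grid,
                             ModelSpec(), CVConfig(n_replicates=3, seed=1))
        assert res.highest_ability == res.table["mean_ability"].max()
        assert res.lowest_ability <= res.highest_ability
        row = res.table[
            (res.table.polynomial_order == res.best.polynomial_order)
            & (res.table.derivative_order == res.best.derivative_order)
            & (res.table.window_size == res.best.window_size)]
        assert row["mean_ability"].iloc[0] == res.highest_ability

    def test_byte_identical_given_seed(self, small_trial):
        spectra, table, _ = small_trial
        grid = [SGParams(2, 1, 29), SGParams(2, 1, 39)]
        args = (spectra, table, "trait", FESConfig(6), grid, ModelSpec(),
                CVConfig(n_replicates=3, seed=9))
        assert grid_search_sg(*args).to_json() == \
            grid_search_sg(*args).to_json()

    def test_requires_filtering_fes(self, small_trial):
        spectra, table, _ = small_trial
        with pytest.raises(ConfigError):
            grid_search_sg(spectra, table, "trait", FESConfig(1),
                           [SGParams()], ModelSpec(), CVConfig())


def _gxe_trial(seed, p_g, p_gl, p_e, sigma2_g=0.3, sigma2_gl=0.6,
               n_genotypes=80, envs=("A", "B")):
    design = ps.generate_design(ps.DesignConfig(
        n_genotypes, list(envs), "single_rep", block_size=10, seed=seed))
    var = VarianceConfig(
        trait=trait_variances(sigma2_g=sigma2_g, sigma2_l=0.2, sigma2_r=0,
                              sigma2_b=0, sigma2_gl=sigma2_gl,
                              sigma2_e=0.05),
        p_g=p_g, p_gl=p_gl, p_e=p_e, link_strength=1.0)
    return ps.simulate_dataset(design, var, SHORT_GRID, seed=seed + 1000)


class TestScenarios:
    def test_scenario1_noise_free(self, noise_free_trial):
        spectra, table, _ = noise_free_trial
        res = scenario1_within_env(spectra, table, "trait", FESConfig(2),
                                   None, ModelSpec(),
                                   CVConfig(n_replicates=5, seed=2))
        assert res.mean > 0.99
        assert len(res.units) == 1

    def test_scenario1_deterministic(self, small_trial):
        spectra, table, _ = small_trial
        args = (spectra, table, "trait", FESConfig(2), None, ModelSpec(),
                CVConfig(n_replicates=3, seed=4))
        assert scenario1_within_env(*args).mean == \
            scenario1_within_env(*args).mean

    def test_scenario2_degenerate_pair_is_in_sample(self, small_trial):
        # B == A: ability equals the in-sample correlation, which is at
        # least the held-out CV ability
        spectra, table, _ = small_trial
        res = scenario2_cross_env(spectra, table, "trait", FESConfig(2),
                                  None, ModelSpec(),
                                  env_pairs=[("E1", "E1")])
        cv_res = scenario1_within_env(spectra, table, "trait", FESConfig(2),
                                      None, ModelSpec(),
                                      CVConfig(n_replicates=5, seed=0),
                                      environments=["E1"])
        assert res.units[0]["ability"] >= cv_res.mean

    def test_scenario2_pure_gxe_near_zero(self):
        abilities = []
        for seed in range(10):
            spectra, table, _ = _gxe_trial(seed, 0.0, 0.9, 0.1)
            res = scenario2_cross_env(spectra, table, "trait",
                                      FESConfig(2), None, ModelSpec())
            abilities.extend(res.abilities)
        assert abs(np.mean(abilities)) < 0.1

    def test_scenario2_no_overlap_raises(self):
        rows = []
        for env, genos in [("A", ["G1", "G2", "G3"]),
                           ("B", ["G4", "G5", "G6"])]:
            for i, g in enumerate(genos):
                rows.append(dict(plot_id=f"{env}{i}", genotype=g,
                                 environment=env, replicate=1, block=1,
                                 trait=float(i)))
        table = pd.DataFrame(rows)
        spectra = ps.SpectraMatrix(
            np.random.default_rng(0).normal(size=(6, 10)),
            table["plot_id"].tolist(), np.arange(1300.0, 1310.0))
        with pytest.raises(ConfigError):
            scenario2_cross_env(spectra, table, "trait", FESConfig(1),
                                None, ModelSpec())

    def test_scenario1_beats_scenario2_under_gxe(self):
        s1m, s2m = [], []
        for seed in range(8):
            spectra, table, _ = _gxe_trial(seed, 0.3, 0.6, 0.1,
                                           sigma2_g=0.3, sigma2_gl=0.6)
            s1 = scenario1_within_env(spectra, table, "trait",
                                      FESConfig(2), None, ModelSpec(),
                                      CVConfig(n_replicates=3, seed=seed))
            s2 = scenario2_cross_env(spectra, table, "trait", FESConfig(2),
                                     None, ModelSpec())
            s1m.append(s1.mean)
            s2m.append(s2.mean)
        assert np.mean(s1m) >= np.mean(s2m)

    def test_scenario3_perfect_link(self, noise_free_trial):
        spectra, table, _ = noise_free_trial
        data = ps.apply_fes(spectra, table, "trait", FESConfig(1))
        X = ps.SpectraMatrix(data.X, data.genotypes, data.wavelengths)
        y = pd.Series(data.y, index=data.genotypes)
        train = X.select_rows(np.arange(0, 100))
        central = X.select_rows(np.arange(100, 150))
        res = scenario3_series(train, y.iloc[:100], central, y, ModelSpec(),
                               use_scaling=False)
        assert res.units[0]["ability"] > 0.99

    def test_scenario3_shuffled_training_near_zero(self):
        # richer spectra (higher rank, noise) so a shuffled-training
        # model cannot stay inside a tiny signal span by chance
        design = ps.generate_design(ps.DesignConfig(
            150, ["E1"], "single_rep", block_size=10, seed=41))
        var = VarianceConfig(
            trait=trait_variances(sigma2_g=1.0, sigma2_l=0, sigma2_r=0,
                                  sigma2_b=0, sigma2_gl=0, sigma2_e=0.3),
            p_g=0.7, p_gl=0.0, p_e=0.3, link_strength=1.0, rank=16)
        spectra, table, _ = ps.simulate_dataset(design, var, SHORT_GRID,
                                                seed=42)
        data = ps.apply_fes(spectra, table, "trait", FESConfig(1))
        X = ps.SpectraMatrix(data.X, data.genotypes, data.wavelengths)
        y_true = pd.Series(data.y, index=data.genotypes)
        rng = np.random.default_rng(11)
        abilities = []
        for _ in range(40):
            y_shuf = pd.Series(rng.permutation(data.y),
                               index=data.genotypes)
            train = X.select_rows(np.arange(0, 100))
            central = X.select_rows(np.arange(100, 150))
            res = scenario3_series(train, y_shuf.iloc[:100], central,
                                   y_true, ModelSpec(), use_scaling=False)
            abilities.append(res.units[0]["ability"])
        assert abs(np.mean(abilities)) < 0.15

    def test_scenario3_missing_blues_raises(self, noise_free_trial):
        spectra, table, _ = noise_free_trial
        data = ps.apply_fes(spectra, table, "trait", FESConfig(1))
        X = ps.SpectraMatrix(data.X, data.genotypes, data.wavelengths)
        y = pd.Series(data.y[:100], index=data.genotypes[:100])
        train = X.select_rows(np.arange(0, 100))
        central = X.select_rows(np.arange(100, 150))
        with pytest.raises(ConfigError):
            scenario3_series(train, y, central, y, ModelSpec())

    def test_scenario3_overlap_warns(self, noise_free_trial):
        spectra, table, _ = noise_free_trial
        data = ps.apply_fes(spectra, table, "trait", FESConfig(1))
        X = ps.SpectraMatrix(data.X, data.genotypes, data.wavelengths)
        y = pd.Series(data.y, index=data.genotypes)
        train = X.select_rows(np.arange(0, 100))
        central = X.select_rows(np.arange(90, 150))
        with pytest.warns(UserWarning, match="both training"):
            scenario3_series(train, y.iloc[:100], central, y, ModelSpec(),
                             use_scaling=False)
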