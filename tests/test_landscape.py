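"""Synthetic landscape and virtual-species generator."""

import numpy as np
import pytest

from sdmbench.grids import GridSpec, read_esri_ascii, write_esri_ascii
from sdmbench.landscape import (
    SpeciesModel,
    Term,
    draw_species_model,
    enumerate_term_pool,
    generate_covariates,
    predict_truth_surface,
    sample_validation_points,
)
from sdmbench.rng import spawn_rng


class TestCovariates:
    def test_layers_are_standardized(self):
        stack = generate_covariates(GridSpec(60, 30), n_cov=5, rng_seed=1)
        assert stack.layers.shape == (5, 30, 60)
        means = stack.layers.reshape(5, -1).mean(axis=1)
        sds = stack.layers.reshape(5, -1).std(axis=1)
        np.testing.assert_allclose(means, 0.0, atol=1e-9)
        np.testing.assert_allclose(sds, 1.0, atol=1e-9)

    def test_same_seed_is_bit_identical(self):
        a = generate_covariates(GridSpec(60, 30), n_cov=3, rng_seed=7)
        b = generate_covariates(GridSpec(60, 30), n_cov=3, rng_seed=7)
        assert np.array_equal(a.layers, b.layers)

    def test_gradient_layers_are_monotone_along_rows(self):
        # search a few seeds for a left-right gradient layer and check
        # monotonicity along every row (monotone map of monotone input)
        found = 0
        for seed in range(40):
            stack = generate_covariates(GridSpec(30, 12), n_cov=1, rng_seed=seed)
            meta = stack.layer_meta[0]
            if meta["kind"] == "gradient" and meta["axis"] == "left-right":
                diffs = np.diff(stack.layers[0], axis=1)
                assert np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)
                found += 1
        assert found >= 3

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_covariates(GridSpec(20, 10), n_cov=0, rng_seed=1)
        with pytest.raises(ValueError):
            GridSpec(4, 10)


class TestTermPool:
    @pytest.mark.parametrize("n_cov,expected", [(5, 20), (1, 2), (2, 5)])
    def test_pool_size(self, n_cov, expected):
        pool = enumerate_term_pool(n_cov)
        assert len(pool) == expected
        assert len(set(pool)) == expected

    def test_interactions_have_ordered_indices(self):
        pool = enumerate_term_pool(4)
        for t in pool:
            if t.kind == "interaction":
                assert t.i < t.j


class TestSpeciesModel:
    def test_term_count_bounds_and_distinctness(self):
        pool = enumerate_term_pool(5)
        for seed in range(20):
            m = draw_species_model(pool, rng_seed=seed)
            assert 1 <= len(m.terms) <= len(pool)
            assert len(set(m.terms)) == len(m.terms)

    def test_terms_selected_uniformly(self):
        # every pool term should appear with equal marginal frequency
        pool = enumerate_term_pool(3)  # 9 terms
        counts = np.zeros(len(pool))
        n_rep = 4000
        rng = spawn_rng(123)
        for _ in range(n_rep):
            m = draw_species_model(pool, rng_seed=rng)
            for t in m.terms:
                counts[pool.index(t)] += 1
        freq = counts / counts.sum()
        # expected uniform across terms; 4 MC sd tolerance
        expected = 1.0 / len(pool)
        assert np.all(np.abs(freq - expected) < 4 * np.sqrt(expected / counts.sum()))

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            draw_species_model([], rng_seed=0)


class TestTruthSurface:
    def test_zero_model_gives_half_everywhere(self, covariates):
        m = SpeciesModel(terms=[Term("linear", 0)], coefficients=[0.0], intercept=0.0)
        t = predict_truth_surface(m, covariates, noise_sd=0.0)
        assert np.allclose(t.p_clean, 0.5)
        assert np.array_equal(t.p_noisy, t.p_clean)

    def test_probabilities_bounded_for_extreme_coefficients(self, covariates):
        m = SpeciesModel(
            terms=[Term("linear", 0), Term("interaction", 0, 1)],
            coefficients=[50.0, -80.0],
            intercept=30.0,
        )
        t = predict_truth_surface(m, covariates, noise_sd=1.0, rng_seed=3)
        for p in (t.p_clean, t.p_noisy):
            assert np.all(p >= 0.0) and np.all(p <= 1.0)

    def test_noise_is_median_preserving_on_logit_scale(self):
        # a cell with logit(p)=0 keeps median 0.5 under symmetric noise
        rng = spawn_rng(9)
        from scipy.special import expit

        draws = expit(rng.normal(0.0, 0.25, 10000))
        assert abs(np.median(draws) - 0.5) < 0.01

    def test_monotone_layer_gives_monotone_probability(self):
        grid = GridSpec(30, 12)
        for seed in range(40):
            stack = generate_covariates(grid, 1, rng_seed=seed)
            meta = stack.layer_meta[0]
            if meta["kind"] == "gradient" and meta["axis"] == "left-right":
                m = SpeciesModel(terms=[Term("linear", 0)], coefficients=[1.5], intercept=0.0)
                t = predict_truth_surface(m, stack, noise_sd=0.0)
                diffs = np.diff(t.p_clean, axis=1)
                assert np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)
                break

    def test_out_of_range_term_rejected(self, covariates):
        m = SpeciesModel(terms=[Term("linear", 99)], coefficients=[1.0], intercept=0.0)
        with pytest.raises(ValueError):
            predict_truth_surface(m, covariates)


class TestValidation:
    def test_count_and_distinct_cells(self, truth):
        v = sample_validation_points(truth, n=300, rng_seed=1)
        assert v.n == 300
        assert len(np.unique(v.points, axis=0)) == 300
        assert truth.grid.contains(v.points).all()

    def test_labels_match_bernoulli_mean(self, covariates):
        m = SpeciesModel(terms=[Term("linear", 0)], coefficients=[0.0], intercept=np.log(0.3 / 0.7))
        t = predict_truth_surface(m, covariates, noise_sd=0.0)
        # p = 0.3 everywhere; label mean within 3 MC standard errors
        v = sample_validation_points(t, n=800, rng_seed=2)
        se = np.sqrt(0.3 * 0.7 / 800)
        assert abs(v.labels.mean() - 0.3) < 3 * se

    def test_per_cell_label_frequency_converges(self, truth):
        # over many seeds the label frequency at a fixed cell approaches p_noisy
        cell_probs = []
        hits = np.zeros(3)
        targets = None
        n_rep = 300
        for seed in range(n_rep):
            v = sample_validation_points(truth, n=truth.grid.n_cells, rng_seed=seed)
            order = np.lexsort(v.points.T)
            pts, labs = v.points[order], v.labels[order]
            if targets is None:
                targets = pts[[10, 200, 500]]
                cell_probs = truth.p_noisy_at(targets)
            for k, tpt in enumerate(targets):
                idx = np.where((pts == tpt).all(axis=1))[0][0]
                hits[k] += labs[idx]
        freq = hits / n_rep
        se = np.sqrt(cell_probs * (1 - cell_probs) / n_rep)
        assert np.all(np.abs(freq - cell_probs) < 4 * se + 1e-9)

    def test_n_larger_than_grid_rejected(self, truth):
        with pytest.raises(ValueError):
            sample_validation_points(truth, n=truth.grid.n_cells + 1)


def test_esri_ascii_roundtrip(tmp_path, truth):
    path = tmp_path / "p.asc"
    write_esri_ascii(path, truth.grid, truth.p_clean)
    grid2, arr = read_esri_ascii(path)
    assert grid2 == truth.grid
    np.testing.assert_allclose(arr, truth.p_clean, rtol=1e-9)
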