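"""Biased occurrence sampling: reporting regions, seeds, clumped draws."""

import numpy as np
import pytest
from scipy.stats import kstest

from sdmbench.grids import GridSpec
from sdmbench.sampling import (
    ClumpingParams,
    SamplingBudgetError,
    SeedSet,
    draw_clumped_samples,
    draw_seed_points,
    filter_seeds,
    generate_reporting_layer,
)
from sdmbench.landscape import SpeciesModel, Term, TruthSurface
from sdmbench.rng import spawn_rng


def _flat_truth(grid, p):
    """Uniform presence-probability surface for mechanism tests."""
    m = SpeciesModel(terms=[Term("linear", 0)], coefficients=[0.0], intercept=0.0)
    arr = np.full((grid.n_rows, grid.n_cols), p)
    return TruthSurface(grid=grid, p_clean=arr, p_noisy=arr, noise_sd=0.0, species_model=m)


class TestReportingLayer:
    def test_six_contiguous_regions_tile_grid(self, grid):
        layer = generate_reporting_layer(grid, rng_seed=3)
        ids = np.unique(layer.region_id)
        assert set(ids) == set(range(1, 7))
        assert np.all((layer.rate >= 0) & (layer.rate <= 1))
        # contiguity: each region is 4-connected
        from scipy.ndimage import label

        for rid in ids:
            _, n_comp = label(layer.region_id == rid)
            assert n_comp == 1

    def test_cell_rate_is_uniform_over_seeds(self, grid):
        rates = [
            generate_reporting_layer(grid, rng_seed=s).rate[5, 5] for s in range(1000)
        ]
        assert kstest(rates, "uniform").pvalue > 0.01


class TestSeeds:
    def test_count_within_bounds(self, grid):
        for seed in range(30):
            s = draw_seed_points(grid, rng_seed=seed, min_seeds=5, max_seeds=20)
            assert 5 <= len(s.points) <= 20
            assert grid.contains(s.points).all()

    def test_single_seed_case(self, grid):
        s = draw_seed_points(grid, rng_seed=0, min_seeds=1, max_seeds=1)
        assert len(s.points) == 1

    def test_count_is_uniform(self, grid):
        rng = spawn_rng(4)
        counts = np.array(
            [len(draw_seed_points(grid, rng, 5, 20).points) for _ in range(4000)]
        )
        freq = np.array([(counts == k).mean() for k in range(5, 21)])
        se = np.sqrt((1 / 16) * (15 / 16) / 4000)
        assert np.all(np.abs(freq - 1 / 16) < 4 * se)

    def test_presence_weighted_seeds_land_in_range(self, grid):
        p = np.zeros((grid.n_rows, grid.n_cols))
        p[:, : grid.n_cols // 2] = 1.0  # species occupies the west half
        truth = _flat_truth(grid, 0.5)
        truth.p_noisy = p
        s = draw_seed_points(grid, rng_seed=1, min_seeds=10, max_seeds=10, truth=truth)
        xmid = grid.origin[0] + grid.width / 2
        assert np.all(s.points[:, 0] < xmid)

    def test_invalid_bounds_rejected(self, grid):
        with pytest.raises(ValueError):
            draw_seed_points(grid, rng_seed=0, min_seeds=0, max_seeds=5)


class TestFilterSeeds:
    def test_rate_one_retains_all(self, grid):
        seeds = draw_seed_points(grid, rng_seed=1, min_seeds=10, max_seeds=10)
        layer = generate_reporting_layer(grid, rng_seed=2)
        layer.region_rates[:] = 1.0
        out = filter_seeds(seeds, layer, rng_seed=3)
        assert out.retained.all()

    def test_rate_zero_force_retains_one(self, grid):
        seeds = draw_seed_points(grid, rng_seed=1, min_seeds=10, max_seeds=10)
        layer = generate_reporting_layer(grid, rng_seed=2)
        layer.region_rates[:] = 0.0
        out = filter_seeds(seeds, layer, rng_seed=3)
        assert out.retained.sum() == 1

    def test_retention_mean_matches_rate(self, grid):
        seeds = draw_seed_points(grid, rng_seed=1, min_seeds=20, max_seeds=20)
        layer = generate_reporting_layer(grid, rng_seed=2)
        layer.region_rates[:] = 0.5
        rng = spawn_rng(9)
        kept = np.array(
            [filter_seeds(seeds, layer, rng).retained.sum() for _ in range(3000)]
        )
        se = np.sqrt(20 * 0.25 / 3000)
        assert abs(kept.mean() - 10) < 4 * se


class TestClumpedSamples:
    def test_exact_count_and_in_grid(self, grid, truth):
        seeds = draw_seed_points(grid, rng_seed=1, min_seeds=5, max_seeds=5, truth=truth)
        s = draw_clumped_samples(seeds, ClumpingParams(3.0), truth, "biological", 25, rng_seed=2)
        assert s.n == 25
        assert grid.contains(s.points).all()
        assert s.bias_mode == "biological"

    def test_small_c_concentrates_near_seed(self, grid):
        truth = _flat_truth(grid, 1.0)
        center = np.array([[grid.width / 2, grid.height / 2]])
        seeds = SeedSet(points=center, retained=np.array([True]))
        s = draw_clumped_samples(seeds, ClumpingParams(1.0), truth, "random", 500, rng_seed=3)
        d = np.linalg.norm(s.points - center, axis=1)
        # distances are |N(1, 0.2)|: essentially all within 2 cells
        assert (d <= 2.0).mean() >= 0.99

    def test_biological_enriches_suitability(self, grid, truth):
        # paired over species-like replicates: mean suitability at
        # biological sample points is at least that of random-effort points
        rng = spawn_rng(17)
        gaps = []
        for rep in range(150):
            seeds = draw_seed_points(grid, rng, 5, 15, truth=truth)
            c = ClumpingParams(float(rng.uniform(1, 10)))
            b = draw_clumped_samples(seeds, c, truth, "biological", 100, rng)
            r = draw_clumped_samples(seeds, c, truth, "random", 100, rng)
            gaps.append(
                truth.p_noisy_at(b.points).mean() - truth.p_noisy_at(r.points).mean()
            )
        gaps = np.array(gaps)
        assert gaps.mean() >= -2 * gaps.std() / np.sqrt(len(gaps))

    def test_unreachable_acceptance_raises_budget_error(self, grid):
        truth = _flat_truth(grid, 0.0)
        seeds = SeedSet(points=np.array([[5.0, 5.0]]), retained=np.array([True]))
        with pytest.raises(SamplingBudgetError):
            draw_clumped_samples(
                seeds, ClumpingParams(2.0), truth, "biological", 25,
                rng_seed=1, attempt_budget_factor=10,
            )

    def test_n_total_bounds_enforced(self, grid, truth):
        seeds = draw_seed_points(grid, rng_seed=1, min_seeds=5, max_seeds=5, truth=truth)
        with pytest.raises(ValueError):
            draw_clumped_samples(seeds, ClumpingParams(2.0), truth, "random", 10, rng_seed=1)

    def test_seeded_determinism_end_to_end(self, grid, truth):
        seeds = draw_seed_points(grid, rng_seed=4, min_seeds=8, max_seeds=8, truth=truth)
        a = draw_clumped_samples(seeds, ClumpingParams(5.0), truth, "random", 60, rng_seed=9)
        b = draw_clumped_samples(seeds, ClumpingParams(5.0), truth, "random", 60, rng_seed=9)
        assert np.array_equal(a.points, b.points)


def test_clumping_params_validate():
    assert ClumpingParams(10.0).c_sd == 2.0
    with pytest.raises(ValueError):
        ClumpingParams(0.5)
    with pytest.raises(ValueError):
        ClumpingParams(51.0)
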