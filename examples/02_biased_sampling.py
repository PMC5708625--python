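"""Draw spatially biased occurrence samples and measure their bias.

Shows the two clumping processes (biological vs random effort), the
six-region reporting filter, and the two diagnostics used to bin
samples into scenarios: the Clark-Evans index (clumping) and convex-hull
coverage (geographic restriction).
"""

from sdmbench import (
    ClumpingParams,
    GridSpec,
    clark_evans_index,
    convex_hull_coverage,
    draw_clumped_samples,
    draw_seed_points,
    draw_species_model,
    enumerate_term_pool,
    filter_seeds,
    generate_covariates,
    generate_reporting_layer,
    predict_truth_surface,
    sample_validation_points,
)

grid = GridSpec(90, 45)
covariates = generate_covariates(grid, 5, rng_seed=2)
model = draw_species_model(enumerate_term_pool(5), rng_seed=30, coef_sd=3.0)
truth = predict_truth_surface(model, covariates, noise_sd=0.25, rng_seed=4)
validation = sample_validation_points(truth, 1000, rng_seed=5)
print(f"species prevalence: {validation.prevalence:.2f}")

reporting = generate_reporting_layer(grid, rng_seed=6)
print("reporting rates by region:", [f"{r:.2f}" for r in reporting.region_rates])

seeds = draw_seed_points(grid, rng_seed=7, truth=truth)
seeds = filter_seeds(seeds, reporting, rng_seed=8)
print(f"seeds: {len(seeds.points)} drawn, {int(seeds.retained.sum())} retained "
      "after the reporting filter")

for c in (2.0, 10.0):
    clump = ClumpingParams(c)
    for mode in ("biological", "random"):
        sample = draw_clumped_samples(seeds, clump, truth, mode, 200, rng_seed=9)
        ce = clark_evans_index(sample.points, grid.area)
        cov = convex_hull_coverage(sample.points, validation.presence_points())
        print(f"c={c:5.1f} {mode:10s}: Clark-Evans {ce:.2f} "
              f"(<1 = clumped), coverage {cov:.2f} of the true range hull")
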