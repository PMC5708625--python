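"""Generate one virtual species and inspect its landscape.

Builds five covariate surfaces on a reduced one-degree world, draws a
random generating regression, and prints summaries of the resulting
true presence-probability surface and validation data.
"""

import numpy as np

from sdmbench import (
    GridSpec,
    draw_species_model,
    enumerate_term_pool,
    generate_covariates,
    predict_truth_surface,
    sample_validation_points,
)

grid = GridSpec(90, 45)  # quarter-resolution world, 1-degree cells
covariates = generate_covariates(grid, n_cov=5, rng_seed=7)
for k, meta in enumerate(covariates.layer_meta):
    print(f"covariate {k}: {meta['kind']:8s} along {meta['axis']}")

pool = enumerate_term_pool(5)
print(f"\ncandidate term pool: {len(pool)} terms "
      "(5 linear + 5 square + 10 pairwise interactions)")

model = draw_species_model(pool, rng_seed=3, coef_sd=3.0)
print(f"species model: {len(model.terms)} terms, intercept {model.intercept:+.2f}")

truth = predict_truth_surface(model, covariates, noise_sd=0.25, rng_seed=11)
occupied = float((truth.p_noisy > 0.5).mean())
print(f"true surface: mean p = {truth.p_noisy.mean():.3f}, "
      f"{occupied:.1%} of cells above 0.5")

validation = sample_validation_points(truth, n=1000, rng_seed=13)
print(f"validation set: {validation.n} points, prevalence {validation.prevalence:.3f}")
print("(prevalence is the fraction of validation points where the species "
      "is actually present; species outside [0.05, 0.5] are redrawn by the "
      "benchmark so ranges stay realistic and AUC stays well-defined)")
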