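# Methods

`sdmbench` is a self-contained simulation study of presence-background
species distribution modelling (SDM) under spatially biased sampling.
Everything is synthetic: the landscape, the species, the sampling
process, and the validation data. This note documents the model and
procedure, the parameters that matter, what the generator emulates and
what it deliberately does not, and the numerical choices.

## The virtual world and virtual species

The landscape is a regular planar grid of square cells (one degree per
cell). The full world is 360 x 180 cells; the package's working default
for tests and the shipped study is a quarter-scale 90 x 45 grid, chosen
so a full factorial run fits in minutes on one CPU. All geometry is
planar in cell units; no geodesic area weighting is applied.

**Covariates.** Five environmental surfaces are generated per species.
Each projects cell centres onto a random axis (left-right, top-bottom
or diagonal), maps the normalized projection onto a random window of a
random Gaussian's support, and takes the Gaussian density there: a
window on one tail yields a monotone gradient, a window spanning the
mode yields a hump — the two qualitative shapes of interpolated
bioclimatic layers. Each layer is standardized to mean 0, sd 1 over
cells (tolerance 1e-9 is asserted in tests).

**True distribution.** The species' presence probability is the
inverse-logit of a regression drawn at random from a candidate pool of
20 terms (5 linear, 5 square, 10 pairwise interactions): a
uniform-random number of terms is selected without replacement and
coefficients and intercept are drawn from a zero-mean Gaussian with
standard deviation `coef_sd = 3.0`. The scale is set by a ceiling
argument: the benchmark's best engines should be able to approach AUC
~0.95 on ideal data, and the AUC of the *true surface itself* (the
Bayes ceiling, since validation labels are Bernoulli draws) is ~0.86 at
`coef_sd = 1` but ~0.96 at `coef_sd = 3`. Per-cell Gaussian noise
(`noise_sd = 0.25`, logit scale) is then added so that covariates never
explain occupancy exactly.

**Species acceptance.** A species is kept only if the prevalence of its
1000-point validation sample lies in [0.05, 0.5]; otherwise the
generating regression is redrawn. The lower bound keeps AUC
well-defined and stable. The upper bound encodes that a realistic
taxon's realised range covers a minority of the landscape: a species
present in ~90% of cells makes the presence-background contrast nearly
uninformative (background "absences" are almost all false), and such
species are not what SDM benchmarks are about.

**Validation data.** 1000 distinct cells drawn uniformly; each label is
a Bernoulli draw from the noisy truth (realised occupancy rather than a
hard threshold).

## The biased sampling process

Occurrence data arise in three stages, mimicking presence-only archives:

1. **Seed records.** A Uniform{5..20} number of seed points; each is an
   occurrence record, i.e. a uniform candidate accepted with
   probability equal to the true (noisy) presence probability at its
   cell. (Without a truth surface, `draw_seed_points` falls back to
   uniform locations.)
2. **Reporting filter.** The landscape is partitioned into six
   contiguous Voronoi regions of six uniform centres, each with a
   Uniform(0,1) reporting rate; each seed survives with its region's
   rate. If none survives, one uniformly chosen seed is force-retained.
3. **Clumped secondary sampling.** Points are dispersed around retained
   seeds: displacement distance |Gaussian(c, c/5)| at a uniform angle,
   off-grid candidates rejected, and every candidate accepted with
   probability equal to the noisy presence probability at its cell —
   occurrence records are observations of the species actually being
   there, in *both* bias modes. The clumping coefficient c is uniform
   on [1, 50] cells on the full-width world and scales proportionally
   with grid width (so [1, 12.5] on the 90-wide grid), preserving the
   dispersal geometry relative to the landscape.

The two clumping processes differ in how *sampling effort* is spread
over seeds: under **biological** clumping effort is homogeneous, so
realised sample density is driven purely by habitat suitability; under
**random** clumping the per-seed effort weights are drawn from a flat
Dirichlet, emulating spatially heterogeneous convenience sampling
unrelated to the landscape. Random effort adds density structure the
covariates cannot explain, which is why it degrades every engine
slightly — the direction this benchmark reproduces.

Rejection sampling has a budget of 1000 x n_total candidate draws;
exhausting it (a species absent around every retained seed) aborts the
sampling stage, and the study driver redraws the species.

## Diagnostics and scenarios

Each sample is summarised by the classical (uncorrected) Clark-Evans
nearest-neighbour index against CSR — evaluated within the sample's own
convex hull, so the index measures *local* clumping — and by convex-hull
coverage: hull area of the sample divided by hull area of the
validation points with presence labels, which captures geographic
restriction. Evaluating CSR within the sample's extent (what R's
spatstat does when given bare coordinates) keeps the two diagnostics
nearly independent, so the median splits (ties to the upper bin)
produce four scenario bins of roughly equal size: even / clumped x
high coverage / restricted. The `clark_evans_index` function itself
takes the study area as an argument, so landscape-window values are one
call away.

## The four engines

All engines see the same presences and the same 1000 random background
points (strategy R by default; SW weights background cells by a
Silverman-bandwidth Gaussian KDE of the presences, ST thins presences
to a 2-cell minimum distance, B combines both).

**Non-spatial Bayesian binomial GLM.** Logistic regression on the
selected covariates plus squares, standardized by the training points;
independent Gaussian(0, 10^2) priors; posterior via the Laplace
approximation (Newton ascent with step halving, gradient tolerance
1e-8); prediction is the inverse-logit at the posterior mode. The mode
preserves the cell ranking that AUC measures.

**Spatial Bayesian GLM with a GMRF field.** Adds a Gaussian Markov
random field u on a regular mesh with node spacing equal to the mesh
cut-off (default 3 degrees, the sweet spot of the engine's own cut-off
sweep for most scenarios), bilinearly projected to data locations and
prediction cells. The precision follows the SPDE construction at
smoothness alpha = 2, Q = tau (kappa^4 C + 2 kappa^2 G + G C^-1 G),
with C the diagonal node-area matrix and G the lattice graph Laplacian;
the effective spatial range is ~sqrt(8)/kappa. Hyperparameters are
selected empirically-Bayes: for each (kappa, tau) on a 5 x 5 log-grid
(factor-2 steps) centred heuristically (range one fifth of the short
landscape axis, unit field variance), the joint (beta, u) mode is found
by Newton ascent with sparse LU solves, and the pair is scored by the
Laplace-approximated marginal likelihood *plus* a penalised-complexity
style exponential prior on the field's marginal standard deviation
(rate 4.6, i.e. ~99% prior mass below sigma = 1 on the logit scale).
Without that hyperprior, maximum-marginal-likelihood selection
reliably picks the widest, strongest field the grid offers and swamps
the fixed effects; a hierarchical Bayesian treatment shrinks the field
toward zero unless the data demand it. The normalised grid scores are
reported as an approximate hyperparameter posterior. Prediction uses
the full linear predictor (fixed effects + projected field) at the
joint mode.

**Boosted regression trees.** A configured call into scikit-learn
gradient boosting with the four standard knobs: learning rate 0.01,
tree depth (complexity) 3, bag fraction 0.75, 1000 trees, on the raw
(linear) covariate design — depth supplies non-linearity and
interactions. No internal early stopping; raising the learning rate or
tree count measurably overfits the sampling clusters in this benchmark.

**MaxEnt-style lasso.** Presences (1) vs background (0) logistic
regression on an expanded feature set — linear, quadratic, pairwise
product, threshold indicators and two-sided hinges at 5 interior
quantile knots, all rescaled to [0,1] — with per-feature L1 penalty
lambda_j = beta sqrt(var_j / n_presence) (variance over presence
points, floored at 1e-6), beta = 1 by default. "Auto features" resolve
by presence count: <10 L; <15 LQ; <80 LQH; else LQHPT. The optimiser is
IRLS with cyclic coordinate descent and soft-thresholding (coefficient
tolerance 1e-6); the intercept is unpenalised.

## Evaluation

AUC is the Mann-Whitney statistic (ties get half credit), computed from
average ranks; an explicit pair-enumeration oracle verifies it in the
tests. Per method x scenario x bias mode, the summary is the mean AUC
across species with a normal-approximation 95% CI (single-species
groups collapse the CI and warn). Method ranking within each of the
eight scenario x bias-mode cells uses mean AUC with ties sharing the
better rank. Sweeps re-fit only the engines a configuration axis
affects, holding everything else at the base configuration.

## Problem sizes

The shipped study (scripts/acceptance.py and the acceptance tests) uses
the 90 x 45 grid with 130 (script) or 100 (tests) species per run, both
bias modes per species, 1000 validation points, and a 50-species
covariate-reduction experiment (a random 2-of-5 subset per species,
seeded). These sizes put roughly 25-55 species in each scenario bin,
giving Monte-Carlo standard errors on cell means of ~0.01-0.02 AUC.

## What passing tests do and do not show

The generator emulates presence-only archives whose density is shaped
by suitability, effort, reporting and dispersal around occurrence loci.
It does *not* emulate: spatially structured residual variation in the
truth (noise is iid on the logit scale), positional error in records,
detection covariates, temporal effort, or niche truncation at range
edges. Two consequences are worth stating plainly. First, because
clustered records here are individually presence-verified, tight clumps
are informative rather than misleading, and the non-spatial GLM
remains competitive with the spatial engine on clumped, high-coverage
samples; benchmarks whose clusters contain contaminated records (or
whose truth has residual spatial structure) will reward the spatial
field more strongly. Second, all accuracy statements are about ranking
(AUC) on Bernoulli-realised validation labels, whose ceiling is set by
the truth surface itself (~0.96 here), not 1.0.

## Known limitations

- Empirical-Bayes grid search with plug-in prediction approximates, but
  is not, full hyperparameter integration; posterior uncertainty in
  (kappa, tau) is reported as grid weights, not propagated.
- The lattice mesh and bilinear projector are a transparent stand-in
  for triangulated finite-element meshes; boundary effects are handled
  only by the mesh extending half a spacing beyond the grid.
- The greedy thinning and the KDE background are order- and
  bandwidth-dependent respectively; both are the field's standard
  simple choices.
- Raster export uses the plain-text ESRI ASCII grid format.
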