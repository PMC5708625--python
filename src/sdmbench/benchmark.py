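"""End-to-end simulation study: virtual species -> biased samples -> four
SDM engines -> scenario-binned AUC.

This module wires the generator, the diagnostics and the engines into
the factorial benchmark: simulate a batch of virtual species with both
clumping processes, fit every engine on each species' occurrence sample
plus background points, score each fit by AUC on the 1000-point
validation set, and bin species into the four clumping x coverage
scenarios by median splits within each bias-mode batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diagnostics import SampleDiagnostics, assign_scenarios, clark_evans_index, convex_hull_coverage
from .engines import (
    BRTSettings,
    DesignSpec,
    GMRFSpec,
    MaxentFeatureSpec,
    build_design,
    fit_brt,
    fit_maxent_like,
    fit_nonspatial_bayes_glm,
    fit_spatial_bayes_glm,
    generate_background,
    thin_presences,
)
from .evaluation import compute_auc, evaluate_species
from .grids import GridSpec
from .landscape import (
    draw_species_model,
    enumerate_term_pool,
    generate_covariates,
    predict_truth_surface,
    sample_validation_points,
)
from .rng import derive_seed, spawn_rng
from .sampling import (
    ClumpingParams,
    SamplingBudgetError,
    draw_clumped_samples,
    draw_seed_points,
    filter_seeds,
    generate_reporting_layer,
)

__all__ = [
    "StudyConfig",
    "SimulatedSpecies",
    "METHODS",
    "simulate_species",
    "simulate_batch",
    "fit_species",
    "fit_evaluate_batch",
    "attach_scenarios",
    "run_benchmark",
    "apply_sweep_level",
]

METHODS = ("spatial_gmrf_glm", "nonspatial_bayes_glm", "brt", "maxent_like")


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of the simulation study, with the study's defaults.

    The defaults are the conditions of the benchmark: a 90x45 reduced
    world at one degree, 5 covariates, logit noise 0.25, 1000 validation
    points, 5-20 seed points, 25-500 occurrence points, clumping
    coefficient uniform on [1, 50], random background of 1000 points.
    """

    grid: GridSpec = field(default_factory=lambda: GridSpec(90, 45))
    n_cov: int = 5
    coef_sd: float = 3.0
    noise_sd: float = 0.25
    n_validation: int = 1000
    prevalence_bounds: tuple[float, float] = (0.05, 0.5)
    min_seeds: int = 5
    max_seeds: int = 20
    n_total_bounds: tuple[int, int] = (25, 500)
    clumping_range: tuple[float, float] | None = None  # None: scale with grid
    bias_modes: tuple[str, ...] = ("biological", "random")
    # engine configuration
    glm_design: DesignSpec = field(default_factory=lambda: DesignSpec(include_squares=True))
    brt_design: DesignSpec = field(default_factory=lambda: DesignSpec(include_squares=False))
    gmrf: GMRFSpec = field(default_factory=GMRFSpec)
    brt: BRTSettings = field(default_factory=BRTSettings)
    maxent: MaxentFeatureSpec = field(default_factory=MaxentFeatureSpec)
    background_strategy: str = "R"
    n_background: int = 1000
    thin_distance: float = 2.0
    max_species_attempts: int = 50

    def resolve_clumping_range(self) -> tuple[float, float]:
        """Clumping range, scaled to the landscape.

        The displacement-distance mean ranges over [1, 50] cells on the
        full 360-cell-wide world; on smaller landscapes the upper end
        scales with grid width so the dispersal geometry relative to
        the landscape is preserved (e.g. [1, 12.5] at width 90).
        """
        if self.clumping_range is not None:
            return self.clumping_range
        hi = max(50.0 * self.grid.width / 360.0, 2.0)
        return (1.0, min(hi, 50.0))


@dataclass
class SimulatedSpecies:
    """One virtual species with its samples and per-sample diagnostics."""

    species_id: str
    covariates: object
    truth: object
    validation: object
    reporting: object
    samples: dict  # bias_mode -> OccurrenceSample
    diagnostics: dict  # bias_mode -> SampleDiagnostics
    seed: int


def _diagnose(sample, validation, grid) -> SampleDiagnostics:
    # Clark-Evans against CSR within the sample's own extent (its convex
    # hull), so the index measures local clumping independently of how
    # much of the landscape the sample spans; geographic restriction is
    # captured separately by the coverage ratio. A degenerate hull
    # (collinear points) is maximal clumping.
    from scipy.spatial import ConvexHull, QhullError

    try:
        window = float(ConvexHull(sample.points).volume)
    except QhullError:
        window = 0.0
    ce = clark_evans_index(sample.points, window) if window > 0 else 0.0
    cov = convex_hull_coverage(sample.points, validation.presence_points())
    return SampleDiagnostics(clark_evans=ce, coverage=cov, n_points=sample.n)


def simulate_species(config: StudyConfig, species_seed: int, species_id: str = "") -> SimulatedSpecies:
    """Simulate one virtual species and its biased occurrence samples.

    Species whose validation prevalence falls outside the configured
    bounds are rejected and redrawn (AUC needs both classes); sampling
    attempts that exhaust the rejection budget (species absent around
    every retained seed) trigger a redraw of the sampling stage.
    """
    grid = config.grid
    pool = enumerate_term_pool(config.n_cov)
    lo, hi = config.prevalence_bounds
    for attempt in range(config.max_species_attempts):
        rngs = {
            name: spawn_rng(species_seed, attempt, k)
            for k, name in enumerate(
                ["cov", "model", "truth", "valid", "report", "seeds", "filter", "samp", "bio", "rand"]
            )
        }
        covariates = generate_covariates(grid, config.n_cov, rngs["cov"])
        model = draw_species_model(pool, rngs["model"], config.coef_sd)
        truth = predict_truth_surface(model, covariates, config.noise_sd, rngs["truth"])
        validation = sample_validation_points(truth, config.n_validation, rngs["valid"])
        if not lo <= validation.prevalence <= hi:
            continue
        if len(validation.presence_points()) < 3:
            continue
        reporting = generate_reporting_layer(grid, rngs["report"])
        seeds = draw_seed_points(grid, rngs["seeds"], config.min_seeds, config.max_seeds, truth=truth)
        seeds = filter_seeds(seeds, reporting, rngs["filter"])
        c_lo, c_hi = config.resolve_clumping_range()
        c = float(rngs["samp"].uniform(c_lo, c_hi))
        n_total = int(rngs["samp"].integers(config.n_total_bounds[0], config.n_total_bounds[1] + 1))
        clumping = ClumpingParams(c=c)
        samples = {}
        try:
            for mode in config.bias_modes:
                samples[mode] = draw_clumped_samples(
                    seeds,
                    clumping,
                    truth,
                    mode,
                    n_total,
                    rngs["bio" if mode == "biological" else "rand"],
                    species_id=species_id,
                )
        except SamplingBudgetError:
            continue
        diagnostics = {
            mode: _diagnose(s, validation, grid) for mode, s in samples.items()
        }
        return SimulatedSpecies(
            species_id=species_id,
            covariates=covariates,
            truth=truth,
            validation=validation,
            reporting=reporting,
            samples=samples,
            diagnostics=diagnostics,
            seed=species_seed,
        )
    raise RuntimeError(
        f"species {species_id!r}: no viable species after "
        f"{config.max_species_attempts} attempts"
    )


def simulate_batch(n_species: int, master_seed: int, config: StudyConfig = StudyConfig()) -> list[SimulatedSpecies]:
    """Simulate a batch; per-species seeds derive from the master seed."""
    return [
        simulate_species(config, derive_seed(master_seed, i), species_id=f"sp{i:04d}")
        for i in range(n_species)
    ]


def fit_species(
    species: SimulatedSpecies,
    bias_mode: str,
    config: StudyConfig = StudyConfig(),
    methods=METHODS,
    rng_seed: int | None = None,
) -> dict:
    """Fit the requested engines on one species' occurrence sample."""
    sample = species.samples[bias_mode]
    grid = config.grid
    if rng_seed is None:
        rng_seed = derive_seed(species.seed, 1000 + (0 if bias_mode == "biological" else 1))

    presences = sample.points
    strategy = config.background_strategy
    if strategy in ("ST", "B"):
        presences = thin_presences(presences, config.thin_distance)
    background = generate_background(
        grid, presences, strategy, config.n_background, spawn_rng(rng_seed, 0)
    )
    points = np.vstack([presences, background.points])
    y = np.concatenate([np.ones(len(presences)), np.zeros(background.n_background)])

    fits = {}
    if "nonspatial_bayes_glm" in methods or "spatial_gmrf_glm" in methods:
        X, transform = build_design(species.covariates, points, config.glm_design)
        if "nonspatial_bayes_glm" in methods:
            fits["nonspatial_bayes_glm"] = fit_nonspatial_bayes_glm(
                y, X, config.gmrf.prior_sd_beta,
                transform=transform, covariates=species.covariates,
            )
        if "spatial_gmrf_glm" in methods:
            fits["spatial_gmrf_glm"] = fit_spatial_bayes_glm(
                y, X, points, grid, config.gmrf,
                transform=transform, covariates=species.covariates,
            )
    if "brt" in methods:
        Xb, tb = build_design(species.covariates, points, config.brt_design)
        fits["brt"] = fit_brt(
            y, Xb, config.brt, rng_seed=derive_seed(rng_seed, 2),
            transform=tb, covariates=species.covariates,
        )
    if "maxent_like" in methods:
        subset = config.glm_design.covariate_subset
        fits["maxent_like"] = fit_maxent_like(
            presences, background, species.covariates, config.maxent,
            covariate_subset=subset,
        )
    return fits


def fit_evaluate_batch(
    batch: list[SimulatedSpecies],
    config: StudyConfig = StudyConfig(),
    methods=METHODS,
    bias_modes=None,
    include_oracle: bool = False,
    progress=None,
) -> pd.DataFrame:
    """Fit and AUC-score every species x bias mode x method.

    Returns tidy rows with the sample diagnostics attached; scenario
    bins are added afterwards by :func:`attach_scenarios`.
    """
    frames = []
    for k, sp in enumerate(batch):
        modes = bias_modes if bias_modes is not None else list(sp.samples)
        for mode in modes:
            fits = fit_species(sp, mode, config, methods)
            res = evaluate_species(fits, sp.validation, species_id=sp.species_id, bias_mode=mode)
            if include_oracle:
                scores = sp.truth.p_noisy_at(sp.validation.points)
                res = pd.concat(
                    [
                        res,
                        pd.DataFrame(
                            [
                                {
                                    "species_id": sp.species_id,
                                    "bias_mode": mode,
                                    "method": "oracle",
                                    "auc": compute_auc(scores, sp.validation.labels),
                                }
                            ]
                        ),
                    ],
                    ignore_index=True,
                )
            d = sp.diagnostics[mode]
            res["clark_evans"] = d.clark_evans
            res["coverage"] = d.coverage
            res["n_points"] = d.n_points
            frames.append(res)
        if progress is not None:
            progress(k + 1, len(batch))
    return pd.concat(frames, ignore_index=True)


def attach_scenarios(results: pd.DataFrame) -> pd.DataFrame:
    """Median-split diagnostics into scenario bins within each bias mode."""
    out = results.copy()
    out["scenario"] = ""
    for mode, grp in out.groupby("bias_mode"):
        per_species = grp.drop_duplicates("species_id").set_index("species_id")
        diags = [
            SampleDiagnostics(row.clark_evans, row.coverage, int(row.n_points))
            for row in per_species.itertuples()
        ]
        assignments = assign_scenarios(diags)
        mapping = {sid: a.scenario for sid, a in zip(per_species.index, assignments)}
        mask = out["bias_mode"] == mode
        out.loc[mask, "scenario"] = out.loc[mask, "species_id"].map(mapping)
    return out


def run_benchmark(
    n_species: int,
    master_seed: int,
    config: StudyConfig = StudyConfig(),
    methods=METHODS,
    include_oracle: bool = False,
    return_batch: bool = False,
    progress=None,
):
    """Simulate, fit, evaluate and scenario-bin a full batch."""
    batch = simulate_batch(n_species, master_seed, config)
    results = fit_evaluate_batch(
        batch, config, methods, include_oracle=include_oracle, progress=progress
    )
    results = attach_scenarios(results)
    if return_batch:
        return results, batch
    return results


def apply_sweep_level(config: StudyConfig, axis: str, level):
    """Return (config at the sweep level, affected methods)."""
    if axis == "background_strategy":
        return replace(config, background_strategy=level), METHODS
    if axis == "covariate_reduction":
        subset = tuple(level) if np.iterable(level) else tuple(range(int(level)))
        return (
            replace(
                config,
                glm_design=replace(config.glm_design, covariate_subset=subset),
                brt_design=replace(config.brt_design, covariate_subset=subset),
            ),
            METHODS,
        )
    if axis == "interactions":
        flag = bool(level)
        return (
            replace(config, glm_design=replace(config.glm_design, include_interactions=flag)),
            ("spatial_gmrf_glm", "nonspatial_bayes_glm"),
        )
    if axis == "maxent_beta":
        return replace(config, maxent=replace(config.maxent, beta=float(level))), ("maxent_like",)
    if axis == "maxent_features":
        classes = frozenset(level) if not isinstance(level, str) else frozenset({level})
        return replace(config, maxent=replace(config.maxent, classes=classes)), ("maxent_like",)
    if axis == "brt_learning_rate":
        return replace(config, brt=replace(config.brt, learning_rate=float(level))), ("brt",)
    if axis == "brt_tree_complexity":
        return replace(config, brt=replace(config.brt, tree_complexity=int(level))), ("brt",)
    if axis == "brt_bag_fraction":
        return replace(config, brt=replace(config.brt, bag_fraction=float(level))), ("brt",)
    if axis == "brt_n_trees":
        return replace(config, brt=replace(config.brt, n_trees=int(level))), ("brt",)
    if axis == "mesh_cutoff":
        return replace(config, gmrf=replace(config.gmrf, mesh_cutoff=float(level))), ("spatial_gmrf_glm",)
    raise ValueError(f"unknown sweep axis {axis!r}")
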