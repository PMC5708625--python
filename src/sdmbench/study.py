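"""The full factorial simulation study and its headline quantities.

This module packages the complete experiment — simulate a batch of
virtual species under both clumping processes, fit the four engines,
bin species into scenarios, and derive the headline quantities:
per-cell mean AUCs, the restricted-scenario extremes, the top-2 method
counts, and the covariate-reduction cost. Both the acceptance script
and the acceptance tests drive this one entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .benchmark import (
    METHODS,
    StudyConfig,
    attach_scenarios,
    fit_evaluate_batch,
    fit_species,
    simulate_batch,
)
from .evaluation import evaluate_species, rank_methods, summarize_by_scenario
from .rng import derive_seed, spawn_rng

__all__ = ["StudyOutcome", "run_factorial_study", "covariate_reduction_drop"]


@dataclass
class StudyOutcome:
    """Everything the factorial study computes."""

    results: pd.DataFrame  # per species x bias mode x method AUC rows
    summaries: pd.DataFrame  # per method x scenario x bias mode means + CIs
    top2_counts: dict  # method -> cells (of 8) ranked in the top 2
    batch: list = field(default_factory=list, repr=False)

    def cell_mean(self, method: str, scenario: str, bias_mode: str) -> float:
        sub = self.summaries[
            (self.summaries.method == method)
            & (self.summaries.scenario == scenario)
            & (self.summaries.bias_mode == bias_mode)
        ]
        if len(sub) != 1:
            raise KeyError(f"no unique cell for ({method}, {scenario}, {bias_mode})")
        return float(sub["mean_auc"].iloc[0])

    def restricted_extremes(self) -> tuple[float, float]:
        """(max, min) method-level mean AUC over the restricted cells."""
        sub = self.summaries[self.summaries.scenario.str.contains("restricted")]
        return float(sub["mean_auc"].max()), float(sub["mean_auc"].min())


def run_factorial_study(
    n_species: int,
    master_seed: int,
    config: StudyConfig = StudyConfig(),
    methods=METHODS,
    keep_batch: bool = True,
    progress=None,
) -> StudyOutcome:
    """Simulate, fit and summarise the full 4-method x 8-cell factorial."""
    batch = simulate_batch(n_species, master_seed, config)
    results = attach_scenarios(
        fit_evaluate_batch(batch, config, methods, progress=progress)
    )
    summaries = summarize_by_scenario(results)
    _, top2 = rank_methods(summaries)
    return StudyOutcome(
        results=results,
        summaries=summaries,
        top2_counts=top2,
        batch=batch if keep_batch else [],
    )


def covariate_reduction_drop(
    outcome: StudyOutcome,
    config: StudyConfig = StudyConfig(),
    methods=METHODS,
    n_species: int = 50,
    subset_size: int = 2,
    bias_mode: str = "biological",
) -> dict:
    """AUC cost of fitting with a reduced covariate subset.

    Refits every engine on the first ``n_species`` of the factorial
    batch using a random ``subset_size``-covariate subset per species
    (seeded from the species seed) and compares against the same
    species' full-design AUCs from the factorial run. Returns per-method
    mean drops and their across-method average.
    """
    if not outcome.batch:
        raise ValueError("outcome must be created with keep_batch=True")
    batch = outcome.batch[: n_species]
    full = outcome.results[
        (outcome.results.bias_mode == bias_mode)
        & (outcome.results.species_id.isin([sp.species_id for sp in batch]))
        & (outcome.results.method.isin(methods))
    ]
    rows = []
    for sp in batch:
        rng = spawn_rng(derive_seed(sp.seed, 777))
        subset = tuple(
            sorted(rng.choice(config.n_cov, size=subset_size, replace=False).tolist())
        )
        reduced_cfg = replace(
            config,
            glm_design=replace(config.glm_design, covariate_subset=subset),
            brt_design=replace(config.brt_design, covariate_subset=subset),
        )
        fits = fit_species(sp, bias_mode, reduced_cfg, methods)
        rows.append(
            evaluate_species(fits, sp.validation, species_id=sp.species_id, bias_mode=bias_mode)
        )
    reduced = pd.concat(rows, ignore_index=True)
    drops = {}
    for m in methods:
        f = full[full.method == m]["auc"].mean()
        r = reduced[reduced.method == m]["auc"].mean()
        drops[m] = float(f - r)
    drops["average"] = float(np.mean([drops[m] for m in methods]))
    return drops
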