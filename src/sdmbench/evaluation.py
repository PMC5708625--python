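"""AUC scoring, scenario aggregation, method ranking and config sweeps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .landscape import ValidationSet

__all__ = [
    "compute_auc",
    "evaluate_species",
    "summarize_by_scenario",
    "rank_methods",
    "SweepGrid",
    "run_sweep",
    "plot_scenario_summary",
]

SWEEP_AXES = (
    "background_strategy",
    "covariate_reduction",
    "interactions",
    "maxent_beta",
    "maxent_features",
    "brt_learning_rate",
    "brt_tree_complexity",
    "brt_bag_fraction",
    "brt_n_trees",
    "mesh_cutoff",
)


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney statistic.

    (concordant pairs + 0.5 * tied pairs) / (n1 * n0) over all
    presence-absence pairs; 0.5 is chance, 1 perfect separation.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)  # average ranks give ties 0.5 credit
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def evaluate_species(models: dict, validation: ValidationSet, species_id: str = "", bias_mode: str = "") -> pd.DataFrame:
    """AUC of each fitted model's surface at the validation points."""
    rows = []
    for name, model in models.items():
        scores = model.scores_at(validation.points, validation.grid)
        try:
            auc = compute_auc(scores, validation.labels)
        except ValueError as exc:
            raise ValueError(f"species {species_id!r}: {exc}") from exc
        rows.append(
            {"species_id": species_id, "bias_mode": bias_mode, "method": name, "auc": auc}
        )
    return pd.DataFrame(rows)


def summarize_by_scenario(results: pd.DataFrame) -> pd.DataFrame:
    """Mean AUC with a normal-approximation 95% CI per method x scenario x bias mode.

    ``results`` must carry columns method, scenario, bias_mode, auc.
    Groups with a single species get a collapsed interval and a warning.
    """
    rows = []
    for (method, scenario, bias_mode), grp in results.groupby(
        ["method", "scenario", "bias_mode"], sort=True
    ):
        aucs = grp["auc"].to_numpy()
        mean = float(aucs.mean())
        if len(aucs) < 2:
            warnings.warn(
                f"single species in group ({method}, {scenario}, {bias_mode}); "
                "confidence interval collapsed to the mean"
            )
            lo = hi = mean
        else:
            half = 1.96 * aucs.std(ddof=1) / np.sqrt(len(aucs))
            lo, hi = mean - half, mean + half
        rows.append(
            {
                "method": method,
                "scenario": scenario,
                "bias_mode": bias_mode,
                "mean_auc": mean,
                "ci_low": lo,
                "ci_high": hi,
                "n_species": len(aucs),
            }
        )
    return pd.DataFrame(rows)


def rank_methods(summaries: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Rank methods by mean AUC within each scenario x bias-mode cell.

    Returns the summaries with a ``rank`` column (ties share the best
    rank, so two methods tied at second both count as top-2) and a dict
    of per-method counts of cells where the method ranks in the top 2.
    """
    out = summaries.copy()
    out["rank"] = (
        out.groupby(["scenario", "bias_mode"])["mean_auc"]
        .rank(method="min", ascending=False)
        .astype(int)
    )
    top2 = (
        out[out["rank"] <= 2].groupby("method").size().reindex(
            out["method"].unique(), fill_value=0
        )
    )
    return out, {m: int(c) for m, c in top2.items()}


@dataclass(frozen=True)
class SweepGrid:
    """One configuration axis and the ordered levels to test."""

    axis: str
    levels: tuple

    def __post_init__(self):
        if self.axis not in SWEEP_AXES:
            raise ValueError(f"unknown sweep axis {self.axis!r}; valid: {SWEEP_AXES}")
        if len(self.levels) < 2:
            raise ValueError("a sweep needs at least 2 levels")


def run_sweep(batch, sweep: SweepGrid, base_config, bias_modes=None, methods=None) -> pd.DataFrame:
    """Re-fit the engines affected by one configuration axis at every level.

    ``batch`` is a list of simulated species (see
    :func:`sdmbench.benchmark.simulate_batch`); everything not on the
    sweep axis is held at ``base_config``. Returns tidy AUC rows with a
    ``config_id`` column identifying the level.
    """
    from . import benchmark  # local import to avoid a module cycle

    frames = []
    for level in sweep.levels:
        config, affected = benchmark.apply_sweep_level(base_config, sweep.axis, level)
        if methods is not None:
            affected = tuple(m for m in affected if m in methods)
            if not affected:
                raise ValueError(
                    f"sweep axis {sweep.axis!r} affects none of the requested methods"
                )
        res = benchmark.fit_evaluate_batch(batch, config, methods=affected, bias_modes=bias_modes)
        res["config_id"] = f"{sweep.axis}={level}"
        res["level"] = [level] * len(res)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def plot_scenario_summary(summaries: pd.DataFrame, path) -> None:
    """Mean AUC with CI whiskers per scenario, one panel per bias mode."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    modes = sorted(summaries["bias_mode"].unique())
    fig, axes = plt.subplots(1, len(modes), figsize=(6 * len(modes), 4), squeeze=False)
    for ax, mode in zip(axes[0], modes):
        sub = summaries[summaries["bias_mode"] == mode]
        scenarios = sorted(sub["scenario"].unique())
        methods = sorted(sub["method"].unique())
        for k, method in enumerate(methods):
            mm = sub[sub["method"] == method].set_index("scenario").reindex(scenarios)
            x = np.arange(len(scenarios)) + 0.15 * (k - (len(methods) - 1) / 2)
            ax.errorbar(
                x,
                mm["mean_auc"],
                yerr=[mm["mean_auc"] - mm["ci_low"], mm["ci_high"] - mm["mean_auc"]],
                fmt="o",
                capsize=3,
                label=method,
            )
        ax.set_xticks(np.arange(len(scenarios)))
        ax.set_xticklabels(scenarios, rotation=20, ha="right")
        ax.set_ylabel("mean AUC")
        ax.set_title(f"{mode} clumping process")
        ax.axhline(0.5, color="grey", lw=0.5)
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
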