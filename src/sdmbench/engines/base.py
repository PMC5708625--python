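"""Common fitted-model container shared by all engines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..landscape import CovariateStack

__all__ = ["FittedSDM", "predict_surface"]


@dataclass
class FittedSDM:
    """A fitted engine: per-cell score surface plus fit diagnostics.

    ``prediction`` is the probability-scale score over the training
    covariate stack's grid, always finite and in [0, 1]. ``scorer``
    re-applies the stored feature transform and model to any compatible
    covariate stack.
    """

    method: str
    prediction: np.ndarray
    fit_info: dict = field(default_factory=dict)
    config: object = None
    scorer: Callable[[CovariateStack], np.ndarray] | None = None
    n_layers: int | None = None

    def scores_at(self, points: np.ndarray, grid) -> np.ndarray:
        rows, cols = grid.point_to_cell(points)
        return self.prediction[rows, cols]


def predict_surface(model: FittedSDM, covariates: CovariateStack) -> np.ndarray:
    """Apply a fitted model to a covariate stack, cell by cell."""
    if model.scorer is None:
        raise ValueError("model does not carry a scorer")
    if model.n_layers is not None and covariates.n_cov != model.n_layers:
        raise ValueError(
            f"model was trained on {model.n_layers} layers, got {covariates.n_cov}"
        )
    surface = np.asarray(model.scorer(covariates), dtype=float)
    if not np.all(np.isfinite(surface)):
        raise ValueError("prediction surface contains non-finite values")
    return np.clip(surface, 0.0, 1.0)
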