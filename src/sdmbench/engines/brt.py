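"""Boosted regression trees engine.

A configured call into scikit-learn's gradient boosting classifier,
exposing the four knobs ecologists usually tune: learning rate, tree
complexity (maximum depth), bag fraction (per-tree subsample) and the
number of trees. Trees see the raw (linear) covariate design; depth
handles non-linearity and interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier

from ..landscape import CovariateStack
from .base import FittedSDM
from .design import DesignTransform

__all__ = ["BRTSettings", "fit_brt"]


@dataclass(frozen=True)
class BRTSettings:
    learning_rate: float = 0.01
    tree_complexity: int = 3
    bag_fraction: float = 0.75
    n_trees: int = 1000

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be at least 1")
        if not 0.0 < self.bag_fraction <= 1.0:
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")


def fit_brt(
    y: np.ndarray,
    X: np.ndarray,
    settings: BRTSettings = BRTSettings(),
    rng_seed: int = 0,
    *,
    transform: DesignTransform | None = None,
    covariates: CovariateStack | None = None,
) -> FittedSDM:
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; cannot fit")
    model = GradientBoostingClassifier(
        learning_rate=settings.learning_rate,
        max_depth=settings.tree_complexity,
        subsample=settings.bag_fraction,
        n_estimators=settings.n_trees,
        random_state=int(rng_seed) % (2**31),
    )
    model.fit(np.asarray(X, dtype=float), y)

    def scorer(stack: CovariateStack) -> np.ndarray:
        if transform is None:
            raise ValueError("model fitted without a design transform")
        Z = transform.transform_cells(stack)
        p = model.predict_proba(Z)[:, 1]
        return p.reshape(stack.grid.n_rows, stack.grid.n_cols)

    prediction = None
    if transform is not None and covariates is not None:
        prediction = scorer(covariates)

    return FittedSDM(
        method="brt",
        prediction=prediction,
        fit_info={"train_score": float(model.train_score_[-1]), "settings": settings},
        config=settings,
        scorer=scorer if transform is not None else None,
        n_layers=covariates.n_cov if covariates is not None else None,
    )
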