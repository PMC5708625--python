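"""Design-matrix construction for the regression engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..landscape import CovariateStack

__all__ = ["DesignSpec", "DesignTransform", "build_design"]


@dataclass(frozen=True)
class DesignSpec:
    """Which covariates and polynomial terms enter a regression design.

    ``covariate_subset`` is None for "all layers" or a tuple of layer
    indices (the covariate-reduction experiments pass 2 of 5 here).
    """

    covariate_subset: tuple[int, ...] | None = None
    include_squares: bool = True
    include_interactions: bool = False

    def resolve_subset(self, n_cov: int) -> tuple[int, ...]:
        if self.covariate_subset is None:
            return tuple(range(n_cov))
        subset = tuple(self.covariate_subset)
        if len(subset) == 0:
            raise ValueError("covariate subset must be non-empty")
        if any(i < 0 or i >= n_cov for i in subset):
            raise ValueError("covariate subset index out of range")
        return subset


@dataclass
class DesignTransform:
    """Frozen training-point feature construction, reusable at predict time."""

    spec: DesignSpec
    subset: tuple[int, ...]
    means: np.ndarray
    sds: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def _raw_features(self, values: np.ndarray) -> np.ndarray:
        """values: (n, n_cov_total) covariate values; returns raw columns."""
        v = values[:, list(self.subset)]
        cols = [v]
        if self.spec.include_squares:
            cols.append(v**2)
        if self.spec.include_interactions:
            k = v.shape[1]
            inter = [v[:, i] * v[:, j] for i in range(k) for j in range(i + 1, k)]
            if inter:
                cols.append(np.column_stack(inter))
        return np.concatenate([np.atleast_2d(c.T).T for c in cols], axis=1)

    def transform(self, values: np.ndarray) -> np.ndarray:
        raw = self._raw_features(values)
        return (raw - self.means) / self.sds

    def transform_points(self, covariates: CovariateStack, points: np.ndarray) -> np.ndarray:
        return self.transform(covariates.values_at(points))

    def transform_cells(self, covariates: CovariateStack) -> np.ndarray:
        layers = covariates.layers
        n_cov = layers.shape[0]
        values = layers.reshape(n_cov, -1).T
        return self.transform(values)


def build_design(
    covariates: CovariateStack, points: np.ndarray, spec: DesignSpec
) -> tuple[np.ndarray, DesignTransform]:
    """Predictor matrix at the given points plus the stored transform.

    Columns are the selected covariates, optionally their squares and
    pairwise products, standardized by the training points' own mean
    and standard deviation (constant columns get unit scale).
    """
    subset = spec.resolve_subset(covariates.n_cov)
    values = covariates.values_at(points)
    names = [f"x{i}" for i in subset]
    if spec.include_squares:
        names += [f"x{i}^2" for i in subset]
    if spec.include_interactions:
        names += [
            f"x{i}*x{j}"
            for a, i in enumerate(subset)
            for j in subset[a + 1 :]
        ]
    tmp = DesignTransform(
        spec=spec,
        subset=subset,
        means=np.zeros(1),
        sds=np.ones(1),
        column_names=names,
    )
    raw = tmp._raw_features(values)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    sds[sds < 1e-12] = 1.0
    tmp.means = means
    tmp.sds = sds
    return tmp.transform(values), tmp
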