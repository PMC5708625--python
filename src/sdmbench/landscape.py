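"""Synthetic landscapes and virtual species.

A virtual species is defined on a regular grid by (i) a stack of
standardized environmental covariate surfaces built from randomly drawn
Gaussian gradients and humps, and (ii) a logistic regression on a random
subset of a candidate term pool (linear, square and pairwise-interaction
terms), giving a true presence-probability surface. Per-cell noise is
added on the logit scale to mimic unmeasured environmental variation,
and a validation set of true presence/absence points is drawn by
Bernoulli sampling of the noisy surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .grids import GridSpec
from .rng import as_rng

__all__ = [
    "Term",
    "CovariateStack",
    "SpeciesModel",
    "TruthSurface",
    "ValidationSet",
    "generate_covariates",
    "enumerate_term_pool",
    "draw_species_model",
    "predict_truth_surface",
    "sample_validation_points",
]


@dataclass(frozen=True)
class Term:
    """One candidate regression term over covariate layers.

    kind is one of {"linear", "square", "interaction"}; ``i`` (and ``j``
    for interactions, with i < j) index covariate layers.
    """

    kind: str
    i: int
    j: int | None = None

    def __post_init__(self):
        if self.kind not in ("linear", "square", "interaction"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "interaction":
            if self.j is None or not self.i < self.j:
                raise ValueError("interaction terms must have i < j")
        elif self.j is not None:
            raise ValueError(f"{self.kind} terms take a single index")

    def evaluate(self, layers: np.ndarray) -> np.ndarray:
        """Evaluate the term over stacked layers (n_cov, ...)."""
        if self.kind == "linear":
            return layers[self.i]
        if self.kind == "square":
            return layers[self.i] ** 2
        return layers[self.i] * layers[self.j]

    def max_index(self) -> int:
        return self.i if self.j is None else max(self.i, self.j)


@dataclass
class CovariateStack:
    """Standardized covariate surfaces sharing one grid.

    ``layers`` has shape (n_cov, n_rows, n_cols); each layer has mean 0
    and standard deviation 1 over cells. ``layer_meta`` records how each
    surface was generated (gradient vs hump, axis, Gaussian parameters).
    """

    grid: GridSpec
    layers: np.ndarray
    layer_meta: list[dict] = field(default_factory=list)

    @property
    def n_cov(self) -> int:
        return self.layers.shape[0]

    def values_at(self, points: np.ndarray) -> np.ndarray:
        """Covariate values at the cells containing points (n, n_cov)."""
        rows, cols = self.grid.point_to_cell(points)
        return self.layers[:, rows, cols].T

    def subset(self, indices) -> "CovariateStack":
        idx = list(indices)
        return CovariateStack(
            grid=self.grid,
            layers=self.layers[idx],
            layer_meta=[self.layer_meta[i] for i in idx] if self.layer_meta else [],
        )


@dataclass
class SpeciesModel:
    """The generating logistic regression of a virtual species."""

    terms: list[Term]
    coefficients: np.ndarray
    intercept: float

    def __post_init__(self):
        if len(self.terms) == 0:
            raise ValueError("species model needs at least one term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in species model")
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.terms),):
            raise ValueError("one coefficient per term required")

    def linear_predictor(self, layers: np.ndarray) -> np.ndarray:
        eta = np.full(layers.shape[1:], self.intercept, dtype=float)
        for coef, term in zip(self.coefficients, self.terms):
            eta += coef * term.evaluate(layers)
        return eta


@dataclass
class TruthSurface:
    """True presence probability of a virtual species, clean and noisy."""

    grid: GridSpec
    p_clean: np.ndarray
    p_noisy: np.ndarray
    noise_sd: float
    species_model: SpeciesModel

    def p_noisy_at(self, points: np.ndarray) -> np.ndarray:
        rows, cols = self.grid.point_to_cell(points)
        return self.p_noisy[rows, cols]


@dataclass
class ValidationSet:
    """True presence/absence labels at random landscape locations."""

    points: np.ndarray  # (n, 2) cell-centre coordinates
    labels: np.ndarray  # (n,) 0/1
    grid: GridSpec

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels must align")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())

    def presence_points(self) -> np.ndarray:
        return self.points[self.labels == 1]


def generate_covariates(grid: GridSpec, n_cov: int = 5, rng_seed=None) -> CovariateStack:
    """Generate ``n_cov`` standardized covariate surfaces.

    Each surface projects cell centres onto a random axis (left-right,
    top-bottom or diagonal), maps the normalized projection onto a
    random window of a random Gaussian's support, and takes the Gaussian
    density there. A window on one tail of the Gaussian yields a
    monotone gradient; a window spanning the mode yields a hump.
    """
    if n_cov < 1:
        raise ValueError("n_cov must be at least 1")
    rng = as_rng(rng_seed)
    xs, ys = grid.center_mesh()
    tx = (xs - grid.origin[0]) / grid.width
    ty = (ys - grid.origin[1]) / grid.height

    layers = np.empty((n_cov, grid.n_rows, grid.n_cols))
    meta: list[dict] = []
    for k in range(n_cov):
        while True:
            mu = rng.normal(0.0, 1.0)
            sigma = rng.uniform(0.5, 2.0)
            axis = rng.choice(["left-right", "top-bottom", "diagonal"])
            if axis == "left-right":
                t = tx
            elif axis == "top-bottom":
                t = ty
            else:
                t = 0.5 * (tx + ty) if rng.random() < 0.5 else 0.5 * (tx + 1.0 - ty)
            if rng.random() < 0.5:
                t = 1.0 - t
            # window on the quantile axis of the Gaussian, at least 0.1 wide
            q0, q1 = np.sort(rng.uniform(0.02, 0.98, size=2))
            if q1 - q0 < 0.1:
                continue
            lo = norm.ppf(q0, loc=mu, scale=sigma)
            hi = norm.ppf(q1, loc=mu, scale=sigma)
            raw = norm.pdf(lo + t * (hi - lo), loc=mu, scale=sigma)
            sd = raw.std()
            if sd < 1e-12:
                continue
            layers[k] = (raw - raw.mean()) / sd
            meta.append(
                {
                    "kind": "hump" if q0 < 0.5 < q1 else "gradient",
                    "axis": str(axis),
                    "mu": float(mu),
                    "sigma": float(sigma),
                    "window": (float(q0), float(q1)),
                }
            )
            break
    return CovariateStack(grid=grid, layers=layers, layer_meta=meta)


def enumerate_term_pool(n_cov: int) -> list[Term]:
    """Ordered candidate pool: linear, square, then pairwise interactions."""
    if n_cov < 1:
        raise ValueError("n_cov must be at least 1")
    pool = [Term("linear", i) for i in range(n_cov)]
    pool += [Term("square", i) for i in range(n_cov)]
    pool += [
        Term("interaction", i, j)
        for i in range(n_cov)
        for j in range(i + 1, n_cov)
    ]
    return pool


def draw_species_model(pool: list[Term], rng_seed=None, coef_sd: float = 1.0) -> SpeciesModel:
    """Draw a random generating regression from the term pool.

    A uniform-random number of terms (at least 1) is selected without
    replacement; coefficients and the intercept are drawn from a
    zero-mean Gaussian with standard deviation ``coef_sd``.
    """
    if len(pool) == 0:
        raise ValueError("term pool must be non-empty")
    if coef_sd <= 0:
        raise ValueError("coef_sd must be positive")
    rng = as_rng(rng_seed)
    k = int(rng.integers(1, len(pool) + 1))
    idx = rng.choice(len(pool), size=k, replace=False)
    terms = [pool[i] for i in sorted(idx)]
    coefs = rng.normal(0.0, coef_sd, size=k)
    intercept = float(rng.normal(0.0, coef_sd))
    return SpeciesModel(terms=terms, coefficients=coefs, intercept=intercept)


def predict_truth_surface(
    model: SpeciesModel,
    covariates: CovariateStack,
    noise_sd: float = 0.25,
    rng_seed=None,
) -> TruthSurface:
    """True presence probability via the inverse-logit of the model.

    ``p_clean`` is the inverse-logit of the linear predictor;
    ``p_noisy`` adds independent Gaussian noise of standard deviation
    ``noise_sd`` on the logit scale per cell (``noise_sd = 0`` leaves
    the surface untouched).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if max(t.max_index() for t in model.terms) >= covariates.n_cov:
        raise ValueError("model term references a missing covariate layer")
    eta = model.linear_predictor(covariates.layers)
    p_clean = expit(eta)
    if noise_sd == 0:
        p_noisy = p_clean.copy()
    else:
        rng = as_rng(rng_seed)
        p_noisy = expit(eta + rng.normal(0.0, noise_sd, size=eta.shape))
    return TruthSurface(
        grid=covariates.grid,
        p_clean=p_clean,
        p_noisy=p_noisy,
        noise_sd=float(noise_sd),
        species_model=model,
    )


def sample_validation_points(truth: TruthSurface, n: int = 1000, rng_seed=None) -> ValidationSet:
    """Draw n distinct cells uniformly; labels are Bernoulli(p_noisy).

    Callers should reject species whose label prevalence falls outside
    [0.05, 0.95] and redraw a new generating model: AUC over a
    single-class or near-single-class validation set is undefined or
    unstable.
    """
    grid = truth.grid
    if n < 2:
        raise ValueError("need at least 2 validation points")
    if n > grid.n_cells:
        raise ValueError("cannot draw more distinct cells than the grid has")
    rng = as_rng(rng_seed)
    idx = rng.choice(grid.n_cells, size=n, replace=False)
    rows, cols = np.divmod(idx, grid.n_cols)
    points = grid.cell_to_center(rows, cols)
    labels = (rng.random(n) < truth.p_noisy[rows, cols]).astype(int)
    return ValidationSet(points=points, labels=labels, grid=grid)
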