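"""MaxEnt-style regularised feature model.

Presences are contrasted against background points with an L1-penalised
logistic regression over an expanded feature set (linear, quadratic,
product, threshold and hinge features of the covariates), with the
per-feature penalty scaled as in MaxEnt's defaults:

    lambda_j = beta * sqrt(var_j / n_presence),

where var_j is the feature's variance over the presence points and beta
is the global regularisation multiplier. Larger beta shrinks more
coefficients to exactly zero, giving simpler models. The "auto
features" class (AF) resolves to a concrete feature set by presence
count, following the published ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from ..landscape import CovariateStack
from .base import FittedSDM
from .background import BackgroundSet

__all__ = [
    "MaxentFeatureSpec",
    "MaxentFeatureExpander",
    "expand_maxent_features",
    "fit_maxent_like",
]

_VALID_CLASSES = {"L", "Q", "P", "T", "H", "AF"}


@dataclass(frozen=True)
class MaxentFeatureSpec:
    classes: frozenset = frozenset({"AF"})
    beta: float = 1.0
    n_knots: int = 5

    def __post_init__(self):
        classes = frozenset(self.classes)
        object.__setattr__(self, "classes", classes)
        unknown = classes - _VALID_CLASSES
        if unknown:
            raise ValueError(f"unknown feature class(es): {sorted(unknown)}")
        if not classes:
            raise ValueError("at least one feature class required")
        if "AF" in classes and len(classes) > 1:
            raise ValueError("AF is exclusive of explicit feature classes")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.n_knots < 2:
            raise ValueError("n_knots must be at least 2")

    def resolve_classes(self, n_presence: int) -> frozenset:
        if "AF" not in self.classes:
            return self.classes
        if n_presence < 10:
            return frozenset({"L"})
        if n_presence < 15:
            return frozenset({"L", "Q"})
        if n_presence < 80:
            return frozenset({"L", "Q", "H"})
        return frozenset({"L", "Q", "H", "P", "T"})


@dataclass
class MaxentFeatureExpander:
    """Feature construction frozen at training time.

    Knots sit at interior quantiles of the training values; every
    feature is affinely rescaled to [0, 1] using the training range.
    """

    classes: frozenset
    knots: np.ndarray  # (n_cov, n_knots) quantile knots per covariate
    lo: np.ndarray = field(default=None)  # per-feature training minima
    hi: np.ndarray = field(default=None)  # per-feature training maxima

    def raw_features(self, values: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(values, dtype=float))
        cols = []
        if "L" in self.classes:
            cols.append(v)
        if "Q" in self.classes:
            cols.append(v**2)
        if "P" in self.classes:
            k = v.shape[1]
            prods = [v[:, i] * v[:, j] for i in range(k) for j in range(i + 1, k)]
            if prods:
                cols.append(np.column_stack(prods))
        if "T" in self.classes:
            t = [
                (v[:, i, None] > self.knots[i][None, :]).astype(float)
                for i in range(v.shape[1])
            ]
            cols.append(np.concatenate(t, axis=1))
        if "H" in self.classes:
            h = []
            for i in range(v.shape[1]):
                diff = v[:, i, None] - self.knots[i][None, :]
                h.append(np.maximum(diff, 0.0))
                h.append(np.maximum(-diff, 0.0))
            cols.append(np.concatenate(h, axis=1))
        return np.concatenate(cols, axis=1)

    def fit_scaling(self, train_values: np.ndarray) -> np.ndarray:
        raw = self.raw_features(train_values)
        self.lo = raw.min(axis=0)
        self.hi = raw.max(axis=0)
        return self._rescale(raw)

    def _rescale(self, raw: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        span = np.where(span < 1e-12, 1.0, span)
        return np.clip((raw - self.lo) / span, 0.0, 1.0)

    def expand(self, values: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise ValueError("expander not fitted; call fit_scaling first")
        return self._rescale(self.raw_features(values))


def expand_maxent_features(
    values: np.ndarray,
    spec: MaxentFeatureSpec,
    n_presence: int | None = None,
) -> tuple[np.ndarray, MaxentFeatureExpander]:
    """Expand covariate values at training points into scaled features.

    ``n_presence`` is required only when the spec uses auto features.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if "AF" in spec.classes and n_presence is None:
        raise ValueError("AF feature class requires n_presence")
    classes = spec.resolve_classes(n_presence if n_presence is not None else 0)
    qs = (np.arange(spec.n_knots) + 1.0) / (spec.n_knots + 1.0)
    knots = np.quantile(v, qs, axis=0).T  # (n_cov, n_knots)
    expander = MaxentFeatureExpander(classes=classes, knots=knots)
    feats = expander.fit_scaling(v)
    return feats, expander


def _l1_logistic_cd(
    y: np.ndarray,
    F: np.ndarray,
    lam: np.ndarray,
    tol: float = 1e-6,
    max_outer: int = 60,
    max_inner: int = 30,
) -> tuple[float, np.ndarray]:
    """Coordinate-descent lasso logistic: min (1/n) nll + sum lam_j |w_j|.

    Outer loop re-weights (IRLS); inner loop cycles soft-threshold
    coordinate updates on the weighted least-squares surrogate. The
    intercept is unpenalised.
    """
    n, J = F.shape
    w = np.zeros(J)
    pbar = np.clip(y.mean(), 1e-4, 1 - 1e-4)
    b = float(logit(pbar))
    eta = np.full(n, b)
    for _ in range(max_outer):
        mu = np.clip(expit(eta), 1e-5, 1 - 1e-5)
        wt = mu * (1.0 - mu) / n
        z = eta + (y - mu) / (mu * (1.0 - mu))
        r = z - eta  # working residual
        denom = wt @ (F**2)
        w_old = w.copy()
        b_old = b
        for _ in range(max_inner):
            delta = 0.0
            # intercept
            b_new = b + (wt @ r) / wt.sum()
            r -= b_new - b
            delta = max(delta, abs(b_new - b))
            b = b_new
            for j in range(J):
                if denom[j] < 1e-12:
                    continue
                rho = wt @ (F[:, j] * r) + denom[j] * w[j]
                wj = np.sign(rho) * max(abs(rho) - lam[j], 0.0) / denom[j]
                if wj != w[j]:
                    r -= F[:, j] * (wj - w[j])
                    delta = max(delta, abs(wj - w[j]))
                    w[j] = wj
            if delta < tol:
                break
        eta = b + F @ w
        if max(np.max(np.abs(w - w_old)), abs(b - b_old)) < tol:
            break
    return b, w


def fit_maxent_like(
    presences: np.ndarray,
    background: BackgroundSet,
    covariates: CovariateStack,
    spec: MaxentFeatureSpec = MaxentFeatureSpec(),
    covariate_subset=None,
) -> FittedSDM:
    """Fit the MaxEnt-style lasso on presences vs background points."""
    pres = np.atleast_2d(np.asarray(presences, dtype=float))
    if len(pres) < 2:
        raise ValueError("need at least 2 presence points")
    if background.n_background == 0:
        raise ValueError("background set is empty")
    stack = covariates if covariate_subset is None else covariates.subset(covariate_subset)
    v_pres = stack.values_at(pres)
    v_back = stack.values_at(background.points)
    values = np.vstack([v_pres, v_back])
    y = np.concatenate([np.ones(len(v_pres)), np.zeros(len(v_back))])
    n_p = len(v_pres)

    F, expander = expand_maxent_features(values, spec, n_presence=n_p)
    if F.std(axis=0).max() < 1e-12:
        raise ValueError("all expanded features are constant; degenerate design")
    var_pres = F[:n_p].var(axis=0)
    lam = spec.beta * np.sqrt(np.maximum(var_pres, 1e-6) / n_p)
    b, w = _l1_logistic_cd(y, F, lam)

    def scorer(s: CovariateStack) -> np.ndarray:
        ss = s if covariate_subset is None else s.subset(covariate_subset)
        vals = ss.layers.reshape(ss.n_cov, -1).T
        eta = b + expander.expand(vals) @ w
        return expit(eta).reshape(s.grid.n_rows, s.grid.n_cols)

    prediction = scorer(covariates)
    return FittedSDM(
        method="maxent_like",
        prediction=prediction,
        fit_info={
            "intercept": b,
            "weights": w,
            "lambda": lam,
            "n_nonzero": int(np.sum(np.abs(w) > 1e-10)),
            "classes": sorted(expander.classes),
            "n_presence": n_p,
        },
        config=spec,
        scorer=scorer,
        n_layers=covariates.n_cov,
    )
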