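"""Non-spatial Bayesian binomial GLM fitted by Laplace approximation.

Logistic regression with independent Gaussian(0, prior_sd_beta^2)
priors on the intercept and coefficients. The posterior is approximated
as a Gaussian centred at the mode (found by Newton ascent with the
exact Hessian) with covariance equal to the inverse negative Hessian
there. Predictions plug in the posterior mode; the benchmark scores
models by AUC, which depends on the ranking of cells only.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from ..landscape import CovariateStack
from .base import FittedSDM
from .design import DesignTransform

__all__ = ["fit_nonspatial_bayes_glm", "laplace_logistic_mode", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    def __init__(self, grad_norm: float):
        super().__init__(f"Newton ascent did not converge; |grad| = {grad_norm:.3g}")
        self.grad_norm = grad_norm


def laplace_logistic_mode(
    y: np.ndarray,
    X: np.ndarray,
    prior_sd: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and covariance of Bayesian logistic regression.

    ``X`` must already contain the intercept column. Returns
    (mode, covariance) where covariance is the Laplace (inverse
    negative-Hessian) approximation at the mode.
    """
    n, p = X.shape
    prior_prec = np.eye(p) / prior_sd**2
    beta = np.zeros(p)
    grad_norm = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu) - prior_prec @ beta
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm < tol:
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = X.T @ (X * w[:, None]) + prior_prec
        step = np.linalg.solve(H, grad)
        # halve the step until the (unimodal) log-posterior improves
        lp0 = _log_posterior(y, X, beta, prior_prec)
        t = 1.0
        while t > 1e-6:
            cand = beta + t * step
            if _log_posterior(y, X, cand, prior_prec) >= lp0:
                break
            t *= 0.5
        beta = beta + t * step
    else:
        if grad_norm >= max(tol, 1e-5):
            raise ConvergenceError(grad_norm)
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = X.T @ (X * w[:, None]) + prior_prec
    cov = np.linalg.inv(H)
    return beta, cov


def _log_posterior(y, X, beta, prior_prec) -> float:
    eta = X @ beta
    # numerically stable Bernoulli log-likelihood
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return ll - 0.5 * float(beta @ prior_prec @ beta)


def fit_nonspatial_bayes_glm(
    y: np.ndarray,
    X: np.ndarray,
    prior_sd_beta: float = 10.0,
    *,
    transform: DesignTransform | None = None,
    covariates: CovariateStack | None = None,
) -> FittedSDM:
    """Fit the non-spatial Bayesian GLM and predict over the landscape.

    ``X`` is the design matrix *without* an intercept column (one is
    added internally and shares the coefficient prior). If ``transform``
    and ``covariates`` are given, the per-cell prediction surface at the
    posterior mode is attached.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; cannot fit")
    Xi = np.column_stack([np.ones(len(y)), X])
    mode, cov = laplace_logistic_mode(y, Xi, prior_sd_beta)
    post_sd = np.sqrt(np.diag(cov))

    def scorer(stack: CovariateStack) -> np.ndarray:
        if transform is None:
            raise ValueError("model fitted without a design transform")
        Z = transform.transform_cells(stack)
        eta = mode[0] + Z @ mode[1:]
        return expit(eta).reshape(stack.grid.n_rows, stack.grid.n_cols)

    prediction = None
    if transform is not None and covariates is not None:
        prediction = scorer(covariates)

    return FittedSDM(
        method="nonspatial_bayes_glm",
        prediction=prediction,
        fit_info={
            "posterior_mode": mode,
            "posterior_cov": cov,
            "posterior_sd": post_sd,
            "prior_sd_beta": prior_sd_beta,
        },
        config=transform.spec if transform is not None else None,
        scorer=scorer if transform is not None else None,
        n_layers=covariates.n_cov if covariates is not None else None,
    )
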