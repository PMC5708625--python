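"""Pseudo-absence (background) strategies and presence thinning.

Strategies follow the usual presence-background toolbox: R draws
background uniformly over the landscape; SW draws background with the
same spatial structure as the presences (cells weighted by a Gaussian
kernel-density estimate of the presence points); ST thins the presences
to a minimum pairwise distance before fitting; B combines SW and ST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from ..grids import GridSpec
from ..rng import as_rng

__all__ = ["BackgroundSet", "generate_background", "thin_presences", "STRATEGIES"]

STRATEGIES = ("R", "SW", "ST", "B")


@dataclass
class BackgroundSet:
    points: np.ndarray  # (n, 2)
    strategy: str

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    @property
    def n_background(self) -> int:
        return len(self.points)


def generate_background(
    grid: GridSpec,
    presences: np.ndarray,
    strategy: str,
    n_background: int = 1000,
    rng_seed=None,
) -> BackgroundSet:
    """Draw background points under strategy R or SW.

    ST and B reuse these spatial draws (R and SW respectively); their
    distinguishing step — thinning the presences — happens on the
    presence side via :func:`thin_presences`.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown background strategy {strategy!r}; valid: {STRATEGIES}")
    if n_background < 10:
        raise ValueError("n_background must be at least 10")
    rng = as_rng(rng_seed)
    xmin, xmax, ymin, ymax = grid.extent

    if strategy in ("R", "ST"):
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, n_background), rng.uniform(ymin, ymax, n_background)]
        )
        return BackgroundSet(points=pts, strategy=strategy)

    # SW / B: cells weighted by a Gaussian KDE of the presences
    pres = np.atleast_2d(np.asarray(presences, dtype=float))
    xs, ys = grid.center_mesh()
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    try:
        kde = gaussian_kde(pres.T, bw_method="silverman")
        w = kde(centers.T)
    except np.linalg.LinAlgError:
        # degenerate presence cloud (collinear); fall back to an
        # axis-wise product of 1D KDEs which preserves the structure
        wx = gaussian_kde(pres[:, 0], bw_method="silverman")(centers[:, 0])
        wy = gaussian_kde(pres[:, 1], bw_method="silverman")(centers[:, 1])
        w = wx * wy
    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        w = np.ones(len(centers))
    w = w / w.sum()
    idx = rng.choice(len(centers), size=n_background, replace=True, p=w)
    return BackgroundSet(points=centers[idx], strategy=strategy)


def thin_presences(presences: np.ndarray, min_distance: float) -> np.ndarray:
    """Greedy spatial thinning in input order.

    A point is kept iff it lies at least ``min_distance`` from every
    point already kept, so the output has all pairwise distances >=
    ``min_distance``.
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be positive")
    pts = np.atleast_2d(np.asarray(presences, dtype=float))
    kept: list[np.ndarray] = []
    tree: cKDTree | None = None
    for p in pts:
        if tree is None:
            kept.append(p)
            tree = cKDTree(np.array(kept))
            continue
        d, _ = tree.query(p)
        if d >= min_distance:
            kept.append(p)
            tree = cKDTree(np.array(kept))
    return np.array(kept)
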