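"""Spatially biased presence-only occurrence sampling.

Occurrence records are simulated in three stages that mimic how real
presence-only datasets arise: (1) a handful of uniform "seed" locations
(expeditions, observer hubs), (2) a six-region reporting-rate filter
(some parts of the world under-report), and (3) secondary sampling
points dispersed around the surviving seeds with a Gaussian clumping
coefficient controlling how tight the clusters are.

Every accepted secondary point is an occurrence record of the species,
so candidates are accepted with probability equal to the true (noisy)
presence probability at their cell. The bias mode controls what drives
*sampling density*: under ``"biological"`` the number of points placed
around each seed is weighted by the suitability at the seed (more
reports where there are more individuals), under ``"random"`` seeds
receive uniform sampling effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec
from .landscape import TruthSurface
from .rng import as_rng

__all__ = [
    "ReportingLayer",
    "SeedSet",
    "ClumpingParams",
    "OccurrenceSample",
    "SamplingBudgetError",
    "generate_reporting_layer",
    "draw_seed_points",
    "filter_seeds",
    "draw_clumped_samples",
]

N_REGIONS = 6


class SamplingBudgetError(RuntimeError):
    """Raised when rejection sampling cannot place the requested points."""


@dataclass
class ReportingLayer:
    """Six contiguous regions, each with its own reporting probability."""

    grid: GridSpec
    region_id: np.ndarray  # (n_rows, n_cols) ints in 1..6
    region_rates: np.ndarray  # (6,) in [0, 1]

    @property
    def rate(self) -> np.ndarray:
        return self.region_rates[self.region_id - 1]

    def rate_at(self, points: np.ndarray) -> np.ndarray:
        rows, cols = self.grid.point_to_cell(points)
        return self.region_rates[self.region_id[rows, cols] - 1]


@dataclass
class SeedSet:
    points: np.ndarray  # (n, 2)
    retained: np.ndarray  # (n,) bool

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.retained = np.asarray(self.retained, dtype=bool)

    def retained_points(self) -> np.ndarray:
        return self.points[self.retained]


@dataclass(frozen=True)
class ClumpingParams:
    """Mean of the seed-to-point displacement-distance Gaussian.

    ``c`` ranges over [1, 50] in cell units; the Gaussian's standard
    deviation is fixed at c/5. Small c means tightly clustered samples.
    """

    c: float

    def __post_init__(self):
        if not 1.0 <= self.c <= 50.0:
            raise ValueError("clumping coefficient must lie in [1, 50]")

    @property
    def c_sd(self) -> float:
        return self.c / 5.0


@dataclass
class OccurrenceSample:
    points: np.ndarray  # (n, 2)
    bias_mode: str  # "biological" | "random"
    clumping: ClumpingParams
    seed_set: SeedSet
    species_id: str = ""

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    @property
    def n(self) -> int:
        return len(self.points)


def generate_reporting_layer(grid: GridSpec, rng_seed=None) -> ReportingLayer:
    """Voronoi partition of the grid into 6 regions with Uniform(0,1) rates.

    Six uniform centre points are drawn and every cell is assigned to
    its nearest centre, which guarantees exactly six contiguous regions
    of random size and placement tiling the landscape.
    """
    rng = as_rng(rng_seed)
    xmin, xmax, ymin, ymax = grid.extent
    centers = np.column_stack(
        [rng.uniform(xmin, xmax, N_REGIONS), rng.uniform(ymin, ymax, N_REGIONS)]
    )
    xs, ys = grid.center_mesh()
    d2 = (xs[..., None] - centers[:, 0]) ** 2 + (ys[..., None] - centers[:, 1]) ** 2
    region_id = np.argmin(d2, axis=-1).astype(np.int64) + 1
    rates = rng.uniform(0.0, 1.0, N_REGIONS)
    return ReportingLayer(grid=grid, region_id=region_id, region_rates=rates)


def draw_seed_points(
    grid: GridSpec,
    rng_seed=None,
    min_seeds: int = 5,
    max_seeds: int = 20,
    truth: TruthSurface | None = None,
) -> SeedSet:
    """A small Uniform{min..max} number of seed locations.

    Without ``truth`` the locations are uniform over the landscape. With
    ``truth`` the seeds are themselves occurrence records of the
    species: uniform candidates are accepted with probability equal to
    the true noisy presence probability at their cell, so seeds land
    where the species actually occurs.
    """
    if not 1 <= min_seeds <= max_seeds:
        raise ValueError("need 1 <= min_seeds <= max_seeds")
    rng = as_rng(rng_seed)
    n = int(rng.integers(min_seeds, max_seeds + 1))
    xmin, xmax, ymin, ymax = grid.extent
    if truth is None:
        pts = np.column_stack([rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)])
    else:
        found: list[np.ndarray] = []
        got = 0
        for _ in range(2000):
            m = max(4 * (n - got), 32)
            cand = np.column_stack(
                [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
            )
            keep = rng.random(m) < truth.p_noisy_at(cand)
            cand = cand[keep]
            if len(cand):
                found.append(cand)
                got += len(cand)
            if got >= n:
                break
        else:
            raise SamplingBudgetError(
                "could not place seed occurrence records; presence "
                "probability is near zero everywhere"
            )
        pts = np.concatenate(found)[:n]
    return SeedSet(points=pts, retained=np.ones(n, dtype=bool))


def filter_seeds(seeds: SeedSet, reporting: ReportingLayer, rng_seed=None) -> SeedSet:
    """Retain each seed with probability equal to its cell's reporting rate.

    If no seed survives, one uniformly chosen seed is force-retained: a
    species with occurrence data must have at least one sampling locus.
    """
    rng = as_rng(rng_seed)
    rates = reporting.rate_at(seeds.points)
    keep = rng.random(len(rates)) < rates
    if not keep.any():
        keep[rng.integers(len(keep))] = True
    return SeedSet(points=seeds.points.copy(), retained=keep)


def draw_clumped_samples(
    seeds: SeedSet,
    clumping: ClumpingParams,
    truth: TruthSurface,
    bias_mode: str,
    n_total: int,
    rng_seed=None,
    attempt_budget_factor: int = 1000,
    species_id: str = "",
) -> OccurrenceSample:
    """Disperse ``n_total`` occurrence points around the retained seeds.

    Candidates are drawn by picking a seed (weighted by suitability at
    the seed under ``bias_mode="biological"``, uniformly under
    ``"random"``), displacing it by a |Gaussian(c, c/5)| distance at a
    uniform angle, discarding off-grid candidates, and accepting the
    remainder with probability equal to the true noisy presence
    probability at the candidate cell (occurrences are records of the
    species actually being there).
    """
    if bias_mode not in ("biological", "random"):
        raise ValueError(f"unknown bias_mode {bias_mode!r}")
    if not 25 <= n_total <= 500:
        raise ValueError("n_total must lie in [25, 500]")
    anchors = seeds.retained_points()
    if len(anchors) == 0:
        raise ValueError("at least one retained seed required")
    rng = as_rng(rng_seed)
    grid = truth.grid

    if bias_mode == "biological":
        # homogeneous effort: realised sample density is driven purely
        # by the suitability of the landscape (via the acceptance step)
        seed_w = np.full(len(anchors), 1.0 / len(anchors))
    else:
        # convenience sampling: spatially heterogeneous effort drawn at
        # random, unrelated to the suitability of the landscape
        seed_w = rng.dirichlet(np.ones(len(anchors)))

    budget = attempt_budget_factor * n_total
    used = 0
    accepted: list[np.ndarray] = []
    n_acc = 0
    while n_acc < n_total:
        m = min(max(4 * (n_total - n_acc), 64), budget - used)
        if m <= 0:
            raise SamplingBudgetError(
                f"could not place {n_total} occurrence points within "
                f"{budget} candidate draws (bias_mode={bias_mode}); the "
                "species may be absent around every retained seed"
            )
        used += m
        sel = rng.choice(len(anchors), size=m, p=seed_w)
        dist = np.abs(rng.normal(clumping.c, clumping.c_sd, m))
        ang = rng.uniform(0.0, 2.0 * np.pi, m)
        cand = anchors[sel] + dist[:, None] * np.column_stack([np.cos(ang), np.sin(ang)])
        inside = grid.contains(cand)
        cand = cand[inside]
        if len(cand) == 0:
            continue
        p = truth.p_noisy_at(cand)
        keep = rng.random(len(cand)) < p
        cand = cand[keep]
        if len(cand):
            accepted.append(cand)
            n_acc += len(cand)
    points = np.concatenate(accepted)[:n_total]
    return OccurrenceSample(
        points=points,
        bias_mode=bias_mode,
        clumping=clumping,
        seed_set=seeds,
        species_id=species_id,
    )
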