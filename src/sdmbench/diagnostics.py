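"""Point-pattern diagnostics and scenario binning.

Each occurrence sample is summarised by two numbers: the Clark–Evans
nearest-neighbour dispersion index (how clumped the points are relative
to complete spatial randomness over the whole landscape) and convex-hull
coverage (how much of the species' true range of occurrence the sample
spans). Batches are split at the within-batch medians of both measures
into the four scenarios used for every method comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

__all__ = [
    "SampleDiagnostics",
    "ScenarioAssignment",
    "DegenerateGeometryError",
    "clark_evans_index",
    "convex_hull_coverage",
    "assign_scenarios",
    "SCENARIOS",
]

SCENARIOS = (
    "even & high coverage",
    "clumped & high coverage",
    "even & restricted",
    "clumped & restricted",
)


class DegenerateGeometryError(ValueError):
    """Fewer than 3 non-collinear points: no hull area exists."""


@dataclass(frozen=True)
class SampleDiagnostics:
    clark_evans: float
    coverage: float
    n_points: int


@dataclass(frozen=True)
class ScenarioAssignment:
    clump_bin: str  # "clumped" | "even"
    coverage_bin: str  # "restricted" | "high_coverage"

    @property
    def scenario(self) -> str:
        a = "clumped" if self.clump_bin == "clumped" else "even"
        b = "restricted" if self.coverage_bin == "restricted" else "high coverage"
        return f"{a} & {b}"


def clark_evans_index(points: np.ndarray, study_area: float) -> float:
    """Clark–Evans dispersion index, uncorrected.

    Ratio of the observed mean nearest-neighbour distance to the
    expectation 1 / (2 sqrt(n / A)) under complete spatial randomness
    over a study region of area ``A``. Values below 1 indicate
    clumping, near 1 randomness, above 1 regularity. No edge
    correction is applied.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if n < 2:
        raise ValueError("Clark-Evans index needs at least 2 points")
    if study_area <= 0:
        raise ValueError("study_area must be positive")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    r_obs = float(dist[:, 1].mean())
    r_exp = 1.0 / (2.0 * np.sqrt(n / study_area))
    return r_obs / r_exp


def _hull_area(points: np.ndarray, what: str) -> float:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise DegenerateGeometryError(f"{what}: need at least 3 points for a hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"{what}: points are collinear") from exc
    return float(hull.volume)  # in 2D, .volume is the polygon area


def convex_hull_coverage(
    sample_points: np.ndarray, true_presence_points: np.ndarray
) -> float:
    """Sample convex-hull area over true-presence convex-hull area.

    The denominator hull is taken over the validation points with
    presence labels — the realised range of occurrence. Low values mean
    the sample is geographically restricted relative to the range.
    """
    a_sample = _hull_area(sample_points, "sample points")
    a_truth = _hull_area(true_presence_points, "true presence points")
    return a_sample / a_truth


def assign_scenarios(diagnostics: list[SampleDiagnostics]) -> list[ScenarioAssignment]:
    """Median-split a batch on both diagnostics into the four scenarios.

    Values strictly below the batch median are "clumped" (Clark–Evans)
    or "restricted" (coverage); values equal to the median go to the
    upper bin (even / high_coverage) so the rule is deterministic.
    """
    if len(diagnostics) < 4:
        raise ValueError("need at least 4 diagnostics to median-split")
    ce = np.array([d.clark_evans for d in diagnostics])
    cov = np.array([d.coverage for d in diagnostics])
    ce_med = float(np.median(ce))
    cov_med = float(np.median(cov))
    return [
        ScenarioAssignment(
            clump_bin="clumped" if c < ce_med else "even",
            coverage_bin="restricted" if v < cov_med else "high_coverage",
        )
        for c, v in zip(ce, cov)
    ]
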