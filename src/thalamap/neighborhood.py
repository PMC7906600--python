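"""Nearest-neighbour-distance statistics and the two-sample KS contrast.

NNDs are computed separately within each cell class and between the two
classes, normalised to the largest NND within each set (per brain), and the
per-brain empirical CDFs are pooled on a common grid (mean ± SEM across
brains).  Segregation of the classes shows up as the between-group CDF
lying below each within-group CDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import kolmogorov


@dataclass(frozen=True)
class TestResult:
    """Generic statistical test outcome (KS D, chi-squared, t, ...)."""

    __test__ = False  # not a pytest class, despite the name

    statistic: float
    p_value: float
    df: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        out = {"statistic": self.statistic, "p_value": self.p_value}
        if self.df is not None:
            out["df"] = self.df
        return out


@dataclass(frozen=True)
class NNDSet:
    """One brain's NND sample for one label (within-A / within-B / between)."""

    label: str
    brain_id: str
    distances: np.ndarray
    normalized: np.ndarray

    @classmethod
    def from_distances(
        cls, label: str, brain_id: str, distances: np.ndarray
    ) -> "NNDSet":
        d = np.asarray(distances, dtype=float)
        if d.size == 0:
            raise ValueError("distances must be non-empty")
        dmax = d.max()
        norm = d / dmax if dmax > 0 else np.ones_like(d)
        return cls(label=label, brain_id=brain_id, distances=d, normalized=norm)


@dataclass(frozen=True)
class CDFSummary:
    """Across-brain mean ± SEM of per-brain empirical CDFs on a [0,1] grid."""

    grid: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_brains: int
    per_brain: np.ndarray  # (n_brains, grid_size)

    @property
    def n_is_1(self) -> bool:
        return self.n_brains == 1


def nnd_within(points: np.ndarray) -> np.ndarray:
    """Per-point Euclidean distance to its nearest other point of the set.

    Duplicate points yield distance 0 (allowed, degenerate case).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least 2 points for within-set NND")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    return dists[:, 1]


def nnd_between(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Bidirectional between-set NND, pooled into one list of |A|+|B| values.

    For every point of A its nearest B neighbour, and vice versa; the result
    is invariant to swapping the set labels (up to ordering).
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both point sets must be non-empty")
    da, _ = cKDTree(b).query(a, k=1)
    db, _ = cKDTree(a).query(b, k=1)
    return np.concatenate([np.atleast_1d(da), np.atleast_1d(db)])


def ecdf_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Empirical CDF (right-continuous step function) evaluated on a grid."""
    v = np.sort(np.asarray(values, dtype=float))
    return np.searchsorted(v, grid, side="right") / len(v)


def pooled_cdf(sets: Sequence[NNDSet], grid_size: int = 256) -> CDFSummary:
    """Across-brain pooled CDF of normalised NNDs on a uniform [0,1] grid.

    Each brain's normalised sample is turned into an empirical CDF on the
    common grid; mean and SEM are taken across brains per grid point.  With
    one brain the SEM is 0 (flagged via ``n_is_1``).
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if not sets:
        raise ValueError("need at least one NNDSet")
    grid = np.linspace(0.0, 1.0, grid_size)
    per_brain = np.array([ecdf_on_grid(s.normalized, grid) for s in sets])
    mean = per_brain.mean(axis=0)
    n = len(sets)
    sem = (
        per_brain.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(grid_size)
    )
    return CDFSummary(grid=grid, mean=mean, sem=sem, n_brains=n, per_brain=per_brain)


def ks_two_sample(sample_a: np.ndarray, sample_b: np.ndarray) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test.

    D = sup_x |F_a(x) − F_b(x)| over the empirical CDFs; the p-value uses
    the asymptotic Kolmogorov distribution with effective sample size
    n_a·n_b/(n_a+n_b).
    """
    a = np.sort(np.asarray(sample_a, dtype=float).ravel())
    b = np.sort(np.asarray(sample_b, dtype=float).ravel())
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    support = np.concatenate([a, b])
    fa = np.searchsorted(a, support, side="right") / len(a)
    fb = np.searchsorted(b, support, side="right") / len(b)
    d = float(np.abs(fa - fb).max())
    en = len(a) * len(b) / (len(a) + len(b))
    p = float(np.clip(kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    return TestResult(statistic=d, p_value=p)


def nnd_analysis(
    points_a: np.ndarray,
    points_b: np.ndarray,
    brain_id: str = "",
) -> dict[str, NNDSet]:
    """The three NND sets of one brain: within-A, within-B, between."""
    return {
        "within-A": NNDSet.from_distances("within-A", brain_id, nnd_within(points_a)),
        "within-B": NNDSet.from_distances("within-B", brain_id, nnd_within(points_b)),
        "between": NNDSet.from_distances(
            "between", brain_id, nnd_between(points_a, points_b)
        ),
    }


def segregation_contrast(
    per_brain_sets: Sequence[dict[str, NNDSet]],
    grid_size: int = 256,
) -> dict:
    """Headline within-vs-between contrast across brains.

    Pools each label's normalised values over brains and runs KS of each
    within-group sample against the between-group sample (pooled variant);
    per-brain KS results are reported alongside.
    """
    if not per_brain_sets:
        raise ValueError("need at least one brain")
    labels = ("within-A", "within-B", "between")
    pooled = {
        lab: np.concatenate([d[lab].normalized for d in per_brain_sets])
        for lab in labels
    }
    cdfs = {
        lab: pooled_cdf([d[lab] for d in per_brain_sets], grid_size) for lab in labels
    }
    result = {
        "cdf": cdfs,
        "ks_pooled": {
            "within-A_vs_between": ks_two_sample(pooled["within-A"], pooled["between"]),
            "within-B_vs_between": ks_two_sample(pooled["within-B"], pooled["between"]),
        },
        "ks_per_brain": [
            {
                "brain_id": d["between"].brain_id,
                "within-A_vs_between": ks_two_sample(
                    d["within-A"].normalized, d["between"].normalized
                ),
                "within-B_vs_between": ks_two_sample(
                    d["within-B"].normalized, d["between"].normalized
                ),
            }
            for d in per_brain_sets
        ],
    }
    return result
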