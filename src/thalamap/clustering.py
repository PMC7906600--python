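"""Spatial k-means, silhouette-based model selection, class composition.

k-means is run on raw µm coordinates (all axes share physical units, so no
standardisation).  Lloyd iterations start from k-means++ seeds, the best of
``n_init`` restarts by inertia is kept, and the within-run inertia sequence
is asserted non-increasing at every step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .core import sem


@dataclass(frozen=True)
class ClusterResult:
    k: int
    labels: np.ndarray
    centroids: np.ndarray  # (k, dim)
    inertia: float
    seed: int
    n_init: int


@dataclass(frozen=True)
class KSelection:
    """Silhouette-vs-k curve and the silhouette-maximising choice of k."""

    k_values: tuple[int, ...]
    silhouettes: tuple[float, ...]          # mean across brains when pooled
    silhouette_sems: tuple[float, ...]
    chosen_k: int
    n_brains: int = 1


@dataclass(frozen=True)
class ClusterComposition:
    """Class make-up of each spatial cluster for one brain."""

    counts: pd.DataFrame       # clusters x classes, integer counts
    fractions: pd.DataFrame    # per-cluster class fractions (rows sum to 1)
    captures: Mapping[str, float]  # class -> fraction in its majority cluster


def _kmeans_pp_init(
    pts: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ seeding: D²-weighted sequential centre choice."""
    n = len(pts)
    centers = np.empty((k, pts.shape[1]))
    centers[0] = pts[rng.integers(n)]
    d2 = ((pts - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[j] = pts[rng.integers(n)]
            continue
        idx = rng.choice(n, p=d2 / total)
        centers[j] = pts[idx]
        d2 = np.minimum(d2, ((pts - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    pts: np.ndarray, centers: np.ndarray, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations until assignments stabilise; inertia must not rise."""
    k = len(centers)
    prev_labels = None
    prev_inertia = np.inf
    for _ in range(max_iter):
        d2 = cdist(pts, centers, metric="sqeuclidean")
        labels = d2.argmin(axis=1)
        # refill empty clusters with the points farthest from their centre
        empty = np.setdiff1d(np.arange(k), np.unique(labels))
        refilled = len(empty) > 0
        if refilled:
            far = np.argsort(-d2[np.arange(len(pts)), labels])
            for j, e in enumerate(empty):
                labels[far[j]] = e
        inertia = float(((pts - centers[labels]) ** 2).sum())
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            break
        for j in range(k):
            mask = labels == j
            if mask.any():
                centers[j] = pts[mask].mean(axis=0)
        new_inertia = float(((pts - centers[labels]) ** 2).sum())
        assert new_inertia <= inertia + 1e-8, "Lloyd inertia increased"
        if not refilled:
            assert new_inertia <= prev_inertia + 1e-8, "Lloyd inertia increased"
        prev_inertia = new_inertia
        prev_labels = labels
    final = float(((pts - centers[labels]) ** 2).sum())
    return labels, centers, final


def kmeans_fit(
    points: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> ClusterResult:
    """Best-of-``n_init`` k-means++ / Lloyd fit; deterministic given seed."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n_distinct = len(np.unique(pts, axis=0))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds number of distinct points ({n_distinct})"
        )
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        centers = _kmeans_pp_init(pts, k, rng)
        labels, centers, inertia = _lloyd(pts, centers.copy())
        if best is None or inertia < best[0]:
            best = (inertia, labels, centers)
    inertia, labels, centers = best
    return ClusterResult(
        k=k,
        labels=labels,
        centroids=centers,
        inertia=inertia,
        seed=seed,
        n_init=n_init,
    )


def silhouette(
    points: np.ndarray, labels: np.ndarray, dist: np.ndarray | None = None
) -> float:
    """Mean per-sample silhouette s = (b − a) / max(a, b).

    a(i): mean distance to the other members of i's cluster; b(i): smallest
    mean distance to any other cluster.  Samples in singleton clusters
    contribute 0 by convention.  ``dist`` optionally supplies a precomputed
    square pairwise-distance matrix.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if len(labels) != len(pts):
        raise ValueError("points and labels length mismatch")
    if dist is None:
        dist = squareform(pdist(pts))
    n = len(pts)
    _, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    sums = np.empty((n, k))
    for j in range(k):
        sums[:, j] = dist[:, inv == j].sum(axis=1)
    counts = np.bincount(inv, minlength=k)
    own_count = counts[inv]
    idx = np.arange(n)
    a = sums[idx, inv] / np.maximum(own_count - 1, 1)
    mean_other = sums / counts
    mean_other[idx, inv] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore"):
        scores = np.where(denom > 0, (b - a) / denom, 0.0)
    scores[own_count == 1] = 0.0  # singleton convention
    return float(scores.mean())


def select_k(
    points: np.ndarray,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> KSelection:
    """Silhouette for each k on the fitted partition; argmax wins, ties → smaller k."""
    pts = np.asarray(points, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    if ks[0] < 2 or ks[-1] > len(pts) - 1:
        raise ValueError(f"k_range must lie within [2, n-1], got {ks[0]}..{ks[-1]}")
    dist = squareform(pdist(pts if pts.ndim == 2 else pts[:, None]))
    sils = []
    for k in ks:
        res = kmeans_fit(pts, k, seed=seed, n_init=n_init)
        sils.append(silhouette(pts, res.labels, dist=dist))
    chosen = ks[int(np.argmax(sils))]  # argmax returns first max → smaller k on ties
    return KSelection(
        k_values=tuple(ks),
        silhouettes=tuple(sils),
        silhouette_sems=tuple(0.0 for _ in ks),
        chosen_k=chosen,
    )


def select_k_multi(
    per_brain_points: Sequence[np.ndarray],
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> KSelection:
    """Per-brain silhouettes averaged across brains; chosen_k maximises the mean.

    Clustering is run separately for each brain; the spread is reported as
    SEM across brains per k.
    """
    if not per_brain_points:
        raise ValueError("need at least one brain")
    selections = [
        select_k(pts, k_range=k_range, seed=seed, n_init=n_init)
        for pts in per_brain_points
    ]
    ks = selections[0].k_values
    mat = np.array([s.silhouettes for s in selections])  # brains x k
    means = mat.mean(axis=0)
    sems = tuple(sem(mat[:, j]) for j in range(mat.shape[1]))
    chosen = ks[int(np.argmax(means))]
    return KSelection(
        k_values=ks,
        silhouettes=tuple(means),
        silhouette_sems=sems,
        chosen_k=chosen,
        n_brains=len(per_brain_points),
    )


def cluster_composition(
    labels: np.ndarray | ClusterResult,
    true_classes: Sequence[str],
) -> ClusterComposition:
    """Cluster × class contingency, per-cluster fractions and per-class capture.

    Capture of a class = largest fraction of that class falling into a
    single cluster (its majority cluster).
    """
    if isinstance(labels, ClusterResult):
        labels = labels.labels
    labels = np.asarray(labels)
    classes = np.asarray(true_classes)
    if len(labels) != len(classes):
        raise ValueError("labels and true_classes length mismatch")
    counts = pd.crosstab(
        pd.Series(labels, name="cluster"), pd.Series(classes, name="class")
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    captures = {
        cls: float((counts[cls] / counts[cls].sum()).max()) for cls in counts.columns
    }
    return ClusterComposition(counts=counts, fractions=fractions, captures=captures)


def capture_summary(
    compositions: Sequence[ClusterComposition],
) -> pd.DataFrame:
    """Across-brain mean ± SEM of per-class majority-cluster capture."""
    if not compositions:
        raise ValueError("need at least one composition")
    classes = sorted({c for comp in compositions for c in comp.captures})
    rows = []
    for cls in classes:
        vals = np.array([comp.captures[cls] for comp in compositions])
        rows.append(
            {
                "class": cls,
                "mean": vals.mean(),
                "sem": sem(vals),
                "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                "n_brains": len(vals),
            }
        )
    return pd.DataFrame(rows).set_index("class")
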