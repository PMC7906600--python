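import numpy as np
import pytest

from thalamap.core import Point3D, RegionAtlas, RegionBox
from thalamap.synthetic import default_atlas, default_two_class_config, simulate_brains


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture
def tiny_atlas():
    """Two overlapping boxes (LP listed before PO) plus a disjoint one."""
    return RegionAtlas(
        boxes=(
            RegionBox("LP", "lateral posterior", (0, 0, 0), (10, 10, 10)),
            RegionBox("PO", "posterior", (5, 0, 0), (15, 10, 10)),
            RegionBox("MD", "mediodorsal", (20, 0, 0), (30, 10, 10)),
        )
    )


@pytest.fixture(scope="session")
def small_brains(atlas):
    """Three small ground-truthed two-class brains (200 cells/class)."""
    cfg = default_two_class_config(seed=42, n_brains=3, n_cells_per_class=200)
    return simulate_brains(cfg)


def brute_force_assign(point: Point3D, atlas: RegionAtlas) -> str:
    """Independent oracle: scan all boxes in order, half-open containment."""
    for box in atlas.boxes:
        inside = True
        for lo, c, hi in zip(
            box.min_corner, (point.x, point.y, point.z), box.max_corner
        ):
            if not (lo <= c < hi):
                inside = False
                break
        if inside:
            return box.region_id
    return "unassigned"


def brute_force_nnd_within(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, float)
    out = np.empty(len(pts))
    for i in range(len(pts)):
        d = np.linalg.norm(pts - pts[i], axis=1)
        d[i] = np.inf
        out[i] = d.min()
    return out


def brute_force_nnd_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    da = [np.linalg.norm(b - p, axis=1).min() for p in a]
    db = [np.linalg.norm(a - p, axis=1).min() for p in b]
    return np.array(da + db)


def brute_force_silhouette(points: np.ndarray, labels) -> float:
    pts = np.asarray(points, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    labels = np.asarray(labels)
    n = len(pts)
    scores = []
    for i in range(n):
        own = np.flatnonzero(labels == labels[i])
        if len(own) == 1:
            scores.append(0.0)
            continue
        a = np.mean(
            [np.linalg.norm(pts[i] - pts[j]) for j in own if j != i]
        )
        b = min(
            np.mean([np.linalg.norm(pts[i] - pts[j]) for j in np.flatnonzero(labels == c)])
            for c in np.unique(labels)
            if c != labels[i]
        )
        denom = max(a, b)
        scores.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(scores))


def brute_force_ks_statistic(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


def brute_force_chi2(table: np.ndarray) -> tuple[float, int]:
    obs = np.asarray(table, float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    stat = ((obs - expected) ** 2 / expected).sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(stat), df


def exhaustive_1d_kmeans(values: np.ndarray, k: int) -> float:
    """Optimal k-means inertia on 1D data by enumerating contiguous splits.

    The optimal 1D k-means partition is contiguous in sorted order, so
    enumerating all C(n-1, k-1) split placements is exhaustive.
    """
    from itertools import combinations

    v = np.sort(np.asarray(values, float))
    n = len(v)
    best = np.inf
    for cuts in combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        inertia = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg = v[lo:hi]
            inertia += ((seg - seg.mean()) ** 2).sum()
        best = min(best, inertia)
    return float(best)


def poisson_disk_points(
    rng: np.random.Generator, n: int, min_dist: float, box: float = 1000.0
) -> np.ndarray:
    """Jittered-grid point set with guaranteed pairwise distance > min_dist."""
    spacing = min_dist * 1.8
    side = int(box // spacing)
    coords = [(i, j, l) for i in range(side) for j in range(side) for l in range(side)]
    pick = rng.choice(len(coords), size=min(n, len(coords)), replace=False)
    pts = np.array([coords[i] for i in pick], float) * spacing
    jitter = rng.uniform(-0.2, 0.2, pts.shape) * spacing
    return pts + jitter + spacing / 2
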