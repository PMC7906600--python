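"""Per-slice centroid extraction and axial-oversampling correction.

Serial optical sectioning detects the same soma on several consecutive
planes.  The correction groups detection events by the transitive closure of
"3D Euclidean distance <= radius" (single linkage) and keeps, per group, the
member on the axially central plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage import measure

from .core import CellRecord, Point3D, RegionAtlas, UNASSIGNED


@dataclass(frozen=True)
class DetectionEvent:
    """One per-optical-slice centroid before deduplication."""

    x_um: float
    y_um: float
    z_plane_um: float
    slice_index: int
    brain_id: str = ""
    source_cell_id: int | None = None  # hidden truth, synthetic data only

    def as_array(self) -> np.ndarray:
        return np.array([self.x_um, self.y_um, self.z_plane_um], dtype=float)


def detect_blobs(
    image: np.ndarray,
    threshold: float,
    min_area_px: int = 1,
    pixel_um: float = 1.0,
) -> np.ndarray:
    """Intensity-weighted centroids of super-threshold connected components.

    Components are 8-connected regions of ``image > threshold`` with area
    >= ``min_area_px``.  Returns an (m, 2) array of (x, y) centroids in µm;
    blobs merged by a low threshold yield a single centroid (documented
    behaviour, not an error).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    image = np.asarray(image, dtype=float)
    mask = image > threshold
    labels = measure.label(mask, connectivity=2)
    centroids = []
    for region in measure.regionprops(labels, intensity_image=image):
        if region.area < min_area_px:
            continue
        row, col = region.centroid_weighted
        centroids.append((col * pixel_um, row * pixel_um))
    if not centroids:
        return np.empty((0, 2), dtype=float)
    return np.array(centroids, dtype=float)


def _group_events(points: np.ndarray, radius: float) -> np.ndarray:
    """Connected-component labels of the <=radius proximity graph."""
    n = len(points)
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def correct_axial_oversampling(
    events: Sequence[DetectionEvent],
    radius: float = 10.0,
    mode: str = "median",
) -> np.ndarray:
    """Collapse repeated axial detections of one soma into one position.

    Events are grouped by the transitive closure of pairwise 3D distance
    <= ``radius``.  With ``mode="median"`` (default) each group is
    represented by its axially central member: members are ordered by
    (z_plane, x, y) and the lower median is kept, which realises the
    "ties -> lower z" rule independently of input order.  ``mode="mean"``
    instead averages the member positions.

    Returns an (m, 3) array of unique-cell positions, m <= len(events).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if mode not in ("median", "mean"):
        raise ValueError(f"mode must be 'median' or 'mean', got {mode!r}")
    if not events:
        return np.empty((0, 3), dtype=float)
    pts = np.array([e.as_array() for e in events])
    labels = _group_events(pts, radius)
    out = []
    for g in np.unique(labels):
        members = pts[labels == g]
        if mode == "mean":
            out.append(members.mean(axis=0))
        else:
            # canonical sort makes the pick permutation-invariant
            order = np.lexsort((members[:, 1], members[:, 0], members[:, 2]))
            out.append(members[order[(len(members) - 1) // 2]])
    out = np.array(out)
    # canonical output order, independent of event arrival order
    return out[np.lexsort((out[:, 1], out[:, 0], out[:, 2]))]


def positions_to_cells(
    positions: np.ndarray,
    brain_id: str,
    class_label: str = "detected",
    genotype: str = "wt",
) -> list[CellRecord]:
    """Wrap corrected (n, 3) positions as :class:`CellRecord` objects."""
    return [
        CellRecord(
            position=Point3D(*map(float, p)),
            class_label=class_label,
            brain_id=brain_id,
            genotype=genotype,
        )
        for p in np.asarray(positions, dtype=float)
    ]


EVENT_COLUMNS = ("brain_id", "slice_index", "z_um", "x_um", "y_um")


def save_events(events: Sequence[DetectionEvent], path) -> None:
    """Write detection events to the standard event CSV."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "brain_id": e.brain_id,
                "slice_index": e.slice_index,
                "z_um": e.z_plane_um,
                "x_um": e.x_um,
                "y_um": e.y_um,
            }
            for e in events
        ],
        columns=list(EVENT_COLUMNS),
    ).to_csv(path, index=False)


def load_events(path) -> list[DetectionEvent]:
    """Read the standard event CSV (brain_id, slice_index, z_um, x_um, y_um)."""
    import pandas as pd

    from .core import FormatError

    df = pd.read_csv(path)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col}")
    return [
        DetectionEvent(
            x_um=float(r.x_um),
            y_um=float(r.y_um),
            z_plane_um=float(r.z_um),
            slice_index=int(r.slice_index),
            brain_id=str(r.brain_id),
        )
        for r in df.itertuples(index=False)
    ]


def count_region(
    cells: Sequence[CellRecord] | np.ndarray,
    atlas: RegionAtlas,
    region_id: str,
) -> int:
    """Number of (corrected) cells assigned to ``region_id``.

    Accepts either CellRecords or a raw (n, 3) position array; assignment
    uses the atlas's first-match-wins half-open containment.
    """
    if region_id not in atlas.region_ids and region_id != UNASSIGNED:
        raise ValueError(f"unknown region_id: {region_id!r}")
    count = 0
    for item in cells:
        p = item.position if isinstance(item, CellRecord) else Point3D(*map(float, item))
        if atlas.assign_point(p) == region_id:
            count += 1
    return count
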