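"""Domain types, coordinate conventions, atlas handling and cell-table I/O.

Coordinate convention (µm everywhere):

* ``x`` — medial → lateral (positive = lateral)
* ``y`` — ventral → dorsal (positive = dorsal)
* ``z`` — caudal → rostral (positive = rostral)

Regions are axis-aligned boxes with half-open containment ``[min, max)`` on
every axis, so a set of face-sharing boxes partitions space without double
counting.  Overlaps are resolved by atlas list order: the first containing
box wins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel region id for cells outside every atlas box.
UNASSIGNED = "unassigned"

#: Mandatory columns of the cell-table CSV (``region_id`` is optional).
CELL_COLUMNS = ("brain_id", "genotype", "x_um", "y_um", "z_um", "class_label")


class FormatError(ValueError):
    """A file does not conform to the declared tabular/JSON format."""


class RowParseError(FormatError):
    """A single data row could not be parsed; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class Point3D:
    """A 3D position in µm in the brain coordinate frame (x=M→L, y=V→D, z=C→R)."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"coordinate {name} must be finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class CellRecord:
    """One classed cell at a 3D position in a named brain."""

    position: Point3D
    class_label: str
    brain_id: str
    genotype: str = "wt"
    region_id: str = UNASSIGNED


@dataclass(frozen=True)
class RegionBox:
    """A named axis-aligned box; containment is half-open, ``[min, max)``."""

    region_id: str
    name: str
    min_corner: tuple[float, float, float]
    max_corner: tuple[float, float, float]

    def __post_init__(self):
        for lo, hi in zip(self.min_corner, self.max_corner):
            if not lo < hi:
                raise ValueError(
                    f"box {self.region_id!r}: min must be < max on every axis "
                    f"({self.min_corner} vs {self.max_corner})"
                )

    def contains(self, p: Point3D) -> bool:
        coords = (p.x, p.y, p.z)
        return all(
            lo <= c < hi
            for lo, c, hi in zip(self.min_corner, coords, self.max_corner)
        )


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered list of :class:`RegionBox`; list order is assignment priority."""

    boxes: tuple[RegionBox, ...]

    def __post_init__(self):
        ids = [b.region_id for b in self.boxes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region ids in atlas: {dupes}")

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(b.region_id for b in self.boxes)

    def assign_point(self, p: Point3D) -> str:
        """Region id of the first containing box, else :data:`UNASSIGNED`."""
        for box in self.boxes:
            if box.contains(p):
                return box.region_id
        return UNASSIGNED

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": [
                {
                    "id": b.region_id,
                    "name": b.name,
                    "min": list(b.min_corner),
                    "max": list(b.max_corner),
                }
                for b in self.boxes
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionAtlas":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"atlas file is not valid JSON: {exc}") from exc
        if "regions" not in payload:
            raise FormatError("atlas JSON missing 'regions' key")
        boxes = []
        for entry in payload["regions"]:
            try:
                boxes.append(
                    RegionBox(
                        region_id=str(entry["id"]),
                        name=str(entry.get("name", entry["id"])),
                        min_corner=tuple(float(v) for v in entry["min"]),
                        max_corner=tuple(float(v) for v in entry["max"]),
                    )
                )
            except KeyError as exc:
                raise FormatError(f"atlas region missing key {exc}") from exc
        return cls(boxes=tuple(boxes))


@dataclass
class BrainDataset:
    """All cells of one brain plus the serial-sampling metadata."""

    brain_id: str
    genotype: str
    cells: list[CellRecord]
    sampling: dict = field(
        default_factory=lambda: {
            "section_thickness_um": 10.0,
            "section_sampling_interval": 1,
        }
    )

    def __post_init__(self):
        for c in self.cells:
            if c.brain_id != self.brain_id:
                raise ValueError(
                    f"cell brain_id {c.brain_id!r} != dataset brain_id "
                    f"{self.brain_id!r}"
                )
        if self.sampling.get("section_sampling_interval", 1) < 1:
            raise ValueError("section_sampling_interval must be >= 1")

    def positions(self, class_label: str | None = None) -> np.ndarray:
        """(n, 3) position array, optionally restricted to one class."""
        cells = self.cells
        if class_label is not None:
            cells = [c for c in cells if c.class_label == class_label]
        if not cells:
            return np.empty((0, 3), dtype=float)
        return np.array([[c.position.x, c.position.y, c.position.z] for c in cells])

    @property
    def class_labels(self) -> list[str]:
        return [c.class_label for c in self.cells]


# ---------------------------------------------------------------------------
# Cell-table I/O
# ---------------------------------------------------------------------------

def load_cell_table(path: str | Path) -> pd.DataFrame:
    """Read the standard cell CSV into a validated DataFrame.

    Required columns: ``brain_id, genotype, x_um, y_um, z_um, class_label``;
    ``region_id`` is optional and defaults to :data:`UNASSIGNED`.  Malformed
    rows raise :class:`RowParseError` with the offending 1-based data-row
    number rather than being dropped silently.
    """
    df = pd.read_csv(path, dtype=str)
    for col in CELL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col}")
    if "region_id" not in df.columns:
        df["region_id"] = UNASSIGNED
    df["region_id"] = df["region_id"].fillna(UNASSIGNED)
    for col in ("x_um", "y_um", "z_um"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise RowParseError(row, f"non-numeric value in column {col}")
        df[col] = parsed.astype(float)
    return df


def _table_to_cells(df: pd.DataFrame) -> list[CellRecord]:
    return [
        CellRecord(
            position=Point3D(r.x_um, r.y_um, r.z_um),
            class_label=r.class_label,
            brain_id=r.brain_id,
            genotype=r.genotype,
            region_id=r.region_id,
        )
        for r in df.itertuples(index=False)
    ]


def load_cells(path: str | Path) -> BrainDataset:
    """Load a single-brain cell CSV as a :class:`BrainDataset`.

    Raises :class:`FormatError` if the file mixes several ``brain_id`` values
    (use :func:`load_brain_datasets` for multi-brain tables).
    """
    df = load_cell_table(path)
    if df.empty:
        return BrainDataset(brain_id="", genotype="", cells=[])
    brains = df["brain_id"].unique()
    if len(brains) > 1:
        raise FormatError(
            f"expected a single brain_id, found {sorted(brains)}; "
            "use load_brain_datasets for multi-brain files"
        )
    genotypes = df["genotype"].unique()
    return BrainDataset(
        brain_id=str(brains[0]),
        genotype=str(genotypes[0]),
        cells=_table_to_cells(df),
    )


def load_brain_datasets(path: str | Path) -> list[BrainDataset]:
    """Load a cell CSV with one or more brains, one dataset per brain."""
    df = load_cell_table(path)
    out = []
    for brain_id, sub in df.groupby("brain_id", sort=True):
        out.append(
            BrainDataset(
                brain_id=str(brain_id),
                genotype=str(sub["genotype"].iloc[0]),
                cells=_table_to_cells(sub),
            )
        )
    return out


def save_cells(datasets: Iterable[BrainDataset], path: str | Path) -> None:
    """Write one or more brain datasets to the standard cell CSV."""
    rows = []
    for ds in datasets:
        for c in ds.cells:
            rows.append(
                {
                    "brain_id": c.brain_id,
                    "genotype": c.genotype,
                    "x_um": c.position.x,
                    "y_um": c.position.y,
                    "z_um": c.position.z,
                    "class_label": c.class_label,
                    "region_id": c.region_id,
                }
            )
    pd.DataFrame(rows, columns=list(CELL_COLUMNS) + ["region_id"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Region assignment and counting
# ---------------------------------------------------------------------------

def assign_regions(
    cells: Sequence[CellRecord], atlas: RegionAtlas
) -> list[CellRecord]:
    """Assign each cell the first atlas box containing it (half-open bounds).

    Returns new records in the input order; cells outside all boxes get
    :data:`UNASSIGNED`.  Assignment is idempotent and order-independent.
    """
    if not atlas.boxes:
        raise ValueError("atlas must contain at least one region")
    if not cells:
        return []
    pts = np.array([[c.position.x, c.position.y, c.position.z] for c in cells])
    assigned = np.full(len(cells), UNASSIGNED, dtype=object)
    unset = np.ones(len(cells), dtype=bool)
    for box in atlas.boxes:
        lo = np.array(box.min_corner)
        hi = np.array(box.max_corner)
        inside = np.all((pts >= lo) & (pts < hi), axis=1) & unset
        assigned[inside] = box.region_id
        unset &= ~inside
    return [replace(c, region_id=assigned[i]) for i, c in enumerate(cells)]


def counts_by_region(dataset: BrainDataset) -> pd.DataFrame:
    """Count cells per (region_id, class_label); totals are conserved.

    ``unassigned`` appears as an ordinary row, so the table sum equals the
    number of cells in the dataset.
    """
    if not dataset.cells:
        return pd.DataFrame()
    df = pd.DataFrame(
        {
            "region_id": [c.region_id for c in dataset.cells],
            "class_label": [c.class_label for c in dataset.cells],
        }
    )
    return pd.crosstab(df["region_id"], df["class_label"])


def distribution_proportions(
    per_brain_counts: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Per-region proportions of one class across brains, mean ± SEM.

    Parameters
    ----------
    per_brain_counts
        ``{brain_id: {region_id: count}}`` for a single cell class.

    Returns
    -------
    DataFrame indexed by region with columns ``mean``, ``sem`` and one
    ``prop_<brain_id>`` column per brain.  Per brain the proportions sum to
    1.  With a single brain the SEM is reported as 0 and the frame carries
    ``attrs["n_is_1"] = True``.
    """
    if not per_brain_counts:
        raise ValueError("need counts for at least one brain")
    counts = pd.DataFrame(per_brain_counts).fillna(0.0)  # regions x brains
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"class total is 0 in brain(s): {sorted(zero.index)}")
    props = counts / totals
    n = props.shape[1]
    out = pd.DataFrame(index=props.index)
    for brain in props.columns:
        out[f"prop_{brain}"] = props[brain]
    out["mean"] = props.mean(axis=1)
    out["sem"] = props.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else 0.0
    out.attrs["n_brains"] = n
    out.attrs["n_is_1"] = n == 1
    return out


def sem(values: np.ndarray | Sequence[float]) -> float:
    """Standard error of the mean; 0 for n == 1 (caller flags n separately)."""
    v = np.asarray(values, dtype=float)
    if v.size <= 1:
        return 0.0
    return float(np.std(v, ddof=1) / np.sqrt(v.size))
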