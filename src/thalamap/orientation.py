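"""Leading-process orientation analysis of migrating cells.

Each migrating cell is reduced to the vector from its soma to the tip of its
leading process, expressed in the brain frame (+x lateral, +y dorsal, +z
rostral).  Orientation is summarised in spherical coordinates with the +z
(rostral) axis as zenith:

* polar angle ``theta = arccos(v_z / |v|)`` in [0, pi]
* azimuth ``phi = atan2(v_y, v_x)`` in (-pi, pi]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import Point3D, sem

#: Anatomical direction names for the sign of each vector component.
AXIS_DIRECTION_NAMES = {
    ("x", "+"): "medio-lateral",
    ("x", "-"): "latero-medial",
    ("y", "+"): "ventro-dorsal",
    ("y", "-"): "dorso-ventral",
    ("z", "+"): "caudo-rostral",
    ("z", "-"): "rostro-caudal",
}


@dataclass(frozen=True)
class LeadingProcessRecord:
    """Soma → process-tip vector of one migrating cell."""

    soma: Point3D
    tip: Point3D
    region_id: str = ""
    stage: str = ""
    brain_id: str = ""
    traceable: bool = True


@dataclass(frozen=True)
class AngularHistogram:
    """2D (theta, phi) bin grid with counts and normalised frequencies."""

    theta_edges: np.ndarray
    phi_edges: np.ndarray
    counts: np.ndarray       # (n_theta, n_phi)
    frequencies: np.ndarray  # counts / n


@dataclass(frozen=True)
class AxisFractions:
    """Per-axis fractions of vectors with positive/negative/zero component."""

    fractions: Mapping[str, float]  # direction name -> fraction
    zero_fractions: Mapping[str, float]  # axis -> fraction exactly 0
    n: int


@dataclass(frozen=True)
class PolarHistogramResult:
    """1D in-plane angle histogram after projection onto a brain plane."""

    plane: str
    bin_edges: np.ndarray
    counts: np.ndarray
    frequencies: np.ndarray
    n_excluded: int  # records whose projection onto the plane was ~zero


def process_vector(record: LeadingProcessRecord):
    """(vector, theta, phi, length) of one record; zero-length is an error."""
    v = record.tip.as_array() - record.soma.as_array()
    length = float(np.linalg.norm(v))
    if length == 0.0:
        raise ValueError(
            f"zero-length leading process (soma == tip) for record in region "
            f"{record.region_id!r}, brain {record.brain_id!r}"
        )
    # atan2 form of arccos(v_z/|v|): well-conditioned near the poles
    theta = float(np.arctan2(np.hypot(v[0], v[1]), v[2]))
    phi = float(np.arctan2(v[1], v[0]))
    return v, theta, phi, length


def vectors_of(records: Sequence[LeadingProcessRecord]) -> np.ndarray:
    """(n, 3) array of soma→tip vectors; rejects zero-length records."""
    return np.array([process_vector(r)[0] for r in records])


def angular_histogram(
    records: Sequence[LeadingProcessRecord],
    n_theta_bins: int = 18,
    n_phi_bins: int = 36,
) -> AngularHistogram:
    """Equal-width 2D histogram over (theta, phi); frequencies sum to 1.

    Bins are right-open, with the last bin closed, so theta = pi and
    phi = pi land in the final bin.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if n_theta_bins < 2 or n_phi_bins < 2:
        raise ValueError("need at least 2 bins on each angular axis")
    angles = np.array([process_vector(r)[1:3] for r in records])
    theta_edges = np.linspace(0.0, np.pi, n_theta_bins + 1)
    phi_edges = np.linspace(-np.pi, np.pi, n_phi_bins + 1)
    counts, _, _ = np.histogram2d(
        angles[:, 0], angles[:, 1], bins=[theta_edges, phi_edges]
    )
    return AngularHistogram(
        theta_edges=theta_edges,
        phi_edges=phi_edges,
        counts=counts,
        frequencies=counts / len(records),
    )


def dominant_axis_fractions(
    records: Sequence[LeadingProcessRecord],
) -> AxisFractions:
    """Fractions of cells oriented along each anatomical half-axis.

    For every axis the fraction of vectors with a strictly positive,
    strictly negative and exactly-zero component is reported under the
    anatomical direction name (e.g. +z → "caudo-rostral"); the three sum to
    1 per axis.  Depends on component signs only, not magnitudes.
    """
    if not records:
        raise ValueError("records must be non-empty")
    vecs = vectors_of(records)
    n = len(vecs)
    fractions = {}
    zeros = {}
    for i, axis in enumerate(("x", "y", "z")):
        comp = vecs[:, i]
        fractions[AXIS_DIRECTION_NAMES[(axis, "+")]] = float((comp > 0).sum() / n)
        fractions[AXIS_DIRECTION_NAMES[(axis, "-")]] = float((comp < 0).sum() / n)
        zeros[axis] = float((comp == 0).sum() / n)
    return AxisFractions(fractions=fractions, zero_fractions=zeros, n=n)


_PLANE_AXES = {"xy": (0, 1), "yz": (1, 2), "xz": (0, 2)}


def polar_histogram(
    records: Sequence[LeadingProcessRecord],
    plane: str = "xy",
    n_bins: int = 36,
) -> PolarHistogramResult:
    """In-plane angle histogram of vectors projected onto a brain plane.

    Records whose projection norm is below ``1e-6 * |v|`` are excluded and
    counted in ``n_excluded``.  Angles are measured from the plane's first
    axis, binned with equal widths over [-pi, pi).
    """
    if plane not in _PLANE_AXES:
        raise ValueError(f"plane must be one of {sorted(_PLANE_AXES)}, got {plane!r}")
    if not records:
        raise ValueError("records must be non-empty")
    ax0, ax1 = _PLANE_AXES[plane]
    vecs = vectors_of(records)
    proj = vecs[:, [ax0, ax1]]
    norms = np.linalg.norm(vecs, axis=1)
    keep = np.linalg.norm(proj, axis=1) >= 1e-6 * norms
    n_excluded = int((~keep).sum())
    proj = proj[keep]
    if len(proj) == 0:
        raise ValueError("no records left after projection filtering")
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    return PolarHistogramResult(
        plane=plane,
        bin_edges=edges,
        counts=counts,
        frequencies=counts / len(proj),
        n_excluded=n_excluded,
    )


def traceable_fraction(
    records: Sequence[LeadingProcessRecord],
) -> dict[str, float]:
    """Per developmental stage, fraction of cells flagged traceable."""
    if not records:
        raise ValueError("records must be non-empty")
    stages: dict[str, list[bool]] = {}
    for r in records:
        stages.setdefault(r.stage, []).append(r.traceable)
    out = {}
    for stage, flags in stages.items():
        if not flags:
            raise ValueError(f"zero records in stage {stage!r}")
        out[stage] = sum(flags) / len(flags)
    return out


def mean_resultant_direction(
    records_or_vectors: Sequence[LeadingProcessRecord] | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Mean direction and mean resultant length of unit orientation vectors.

    Returns ``(unit mean direction, R)`` where R in [0, 1] is the norm of
    the average unit vector (1 = perfectly aligned, ~0 = uniform).
    """
    if isinstance(records_or_vectors, np.ndarray):
        vecs = np.asarray(records_or_vectors, dtype=float)
    else:
        vecs = vectors_of(list(records_or_vectors))
    units = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    mean_vec = units.mean(axis=0)
    r = float(np.linalg.norm(mean_vec))
    if r == 0.0:
        raise ValueError("mean resultant length is 0; direction undefined")
    return mean_vec / r, r


PROCESS_COLUMNS = (
    "brain_id",
    "stage",
    "region_id",
    "soma_x_um",
    "soma_y_um",
    "soma_z_um",
    "tip_x_um",
    "tip_y_um",
    "tip_z_um",
    "traceable",
)


def save_processes(records: Sequence[LeadingProcessRecord], path) -> None:
    """Write leading-process records to the standard process CSV."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "brain_id": r.brain_id,
                "stage": r.stage,
                "region_id": r.region_id,
                "soma_x_um": r.soma.x,
                "soma_y_um": r.soma.y,
                "soma_z_um": r.soma.z,
                "tip_x_um": r.tip.x,
                "tip_y_um": r.tip.y,
                "tip_z_um": r.tip.z,
                "traceable": r.traceable,
            }
            for r in records
        ],
        columns=list(PROCESS_COLUMNS),
    ).to_csv(path, index=False)


def load_processes(path) -> list[LeadingProcessRecord]:
    """Read the standard process CSV back into records."""
    import pandas as pd

    from .core import FormatError

    df = pd.read_csv(path)
    for col in PROCESS_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col}")
    return [
        LeadingProcessRecord(
            soma=Point3D(float(r.soma_x_um), float(r.soma_y_um), float(r.soma_z_um)),
            tip=Point3D(float(r.tip_x_um), float(r.tip_y_um), float(r.tip_z_um)),
            region_id=str(r.region_id),
            stage=str(r.stage),
            brain_id=str(r.brain_id),
            traceable=bool(r.traceable),
        )
        for r in df.itertuples(index=False)
    ]


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two 3-vectors."""
    u = np.asarray(u, float) / np.linalg.norm(u)
    v = np.asarray(v, float) / np.linalg.norm(v)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))
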