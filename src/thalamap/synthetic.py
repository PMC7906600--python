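"""Seeded generators for ground-truthed synthetic inputs.

Every generator is a pure function of (config, seed): repeated calls with
the same arguments return identical output.  Randomness always flows through
one locally constructed ``numpy.random.Generator``; no global RNG state is
touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import vonmises_fisher

from .core import BrainDataset, CellRecord, Point3D, RegionAtlas, RegionBox, assign_regions
from .detection import DetectionEvent
from .orientation import LeadingProcessRecord


# ---------------------------------------------------------------------------
# Default stylized atlas and two-class spatial model
# ---------------------------------------------------------------------------

def default_atlas() -> RegionAtlas:
    """Stylized box atlas with six named nuclei plus a catch-all.

    Specific nuclei come first so the overlapping ``other_TC`` box (covering
    the whole volume) only captures leftovers — exercising first-match-wins
    ordering on every assignment.
    """
    boxes = [
        # caudal third: lateral LGd, medial VP
        RegionBox("LGd", "dorsal lateral geniculate", (1000, 0, 0), (2000, 1000, 667)),
        RegionBox("VP", "ventral posterior", (0, 0, 0), (1000, 1000, 667)),
        # middle third: lateral LP, medial PO
        RegionBox("LP", "lateral posterior", (1000, 0, 667), (2000, 1000, 1333)),
        RegionBox("PO", "posterior complex", (0, 0, 667), (1000, 1000, 1333)),
        # rostral third: lateral LD, medial MD
        RegionBox("LD", "lateral dorsal", (1000, 0, 1333), (2000, 1000, 2000)),
        RegionBox("MD", "mediodorsal", (0, 0, 1333), (1000, 1000, 2000)),
        RegionBox("other_TC", "other thalamocortical", (0, 0, 0), (2000, 1000, 2000)),
    ]
    return RegionAtlas(boxes=tuple(boxes))


@dataclass(frozen=True)
class GaussianComponent:
    """One isotropic/diagonal 3D Gaussian blob of a class's spatial model."""

    mean: Point3D
    sd: tuple[float, float, float]
    weight: float

    def __post_init__(self):
        if any(s <= 0 for s in self.sd):
            raise ValueError("component SDs must be > 0")
        if self.weight < 0:
            raise ValueError("component weight must be >= 0")


@dataclass(frozen=True)
class ClassSpatialModel:
    components: tuple[GaussianComponent, ...]
    n_cells: int

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        total = sum(c.weight for c in self.components)
        if self.components and abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total}")


@dataclass(frozen=True)
class SyntheticBrainConfig:
    """Ground-truthed two-class (or k-class) brain generator settings."""

    seed: int
    n_brains: int
    class_models: Mapping[str, ClassSpatialModel]
    atlas: RegionAtlas
    genotype: str = "het"


def default_two_class_config(
    seed: int,
    n_brains: int = 3,
    n_cells_per_class: int = 1000,
    sd_um: float = 150.0,
    atlas: RegionAtlas | None = None,
) -> SyntheticBrainConfig:
    """Two classes with distinct enrichment: A caudal, B rostro-medial.

    Class-mean separation along z is ~1200 µm = 8x the default within-class
    SD, comfortably above the 4x regime where spatial clustering separates
    the classes.
    """
    atlas = atlas or default_atlas()
    iso = (sd_um, sd_um, sd_um)
    class_a = ClassSpatialModel(
        components=(
            GaussianComponent(Point3D(1150, 500, 400), iso, 0.6),   # LGd-ish
            GaussianComponent(Point3D(750, 500, 400), iso, 0.4),    # VP-ish
        ),
        n_cells=n_cells_per_class,
    )
    class_b = ClassSpatialModel(
        components=(
            GaussianComponent(Point3D(700, 600, 1600), iso, 0.7),   # MD-ish
            GaussianComponent(Point3D(1100, 500, 1600), iso, 0.3),  # LD-ish
        ),
        n_cells=n_cells_per_class,
    )
    return SyntheticBrainConfig(
        seed=seed,
        n_brains=n_brains,
        class_models={"classA": class_a, "classB": class_b},
        atlas=atlas,
    )


def simulate_two_class_brain(
    config: SyntheticBrainConfig, brain_index: int
) -> BrainDataset:
    """Sample one brain's cells from the per-class Gaussian mixtures.

    Deterministic given (config.seed, brain_index).  Each cell carries its
    true class in ``class_label`` and its atlas region in ``region_id``.
    """
    total = sum(m.n_cells for m in config.class_models.values())
    if total == 0:
        raise ValueError("config yields zero total cells")
    rng = np.random.default_rng([config.seed, brain_index])
    brain_id = f"brain{brain_index:02d}"
    cells: list[CellRecord] = []
    for label in sorted(config.class_models):
        model = config.class_models[label]
        if model.n_cells == 0:
            continue
        weights = np.array([c.weight for c in model.components])
        choice = rng.choice(len(model.components), size=model.n_cells, p=weights)
        for ci in choice:
            comp = model.components[ci]
            pos = rng.normal(comp.mean.as_array(), np.array(comp.sd))
            cells.append(
                CellRecord(
                    position=Point3D(*pos),
                    class_label=label,
                    brain_id=brain_id,
                    genotype=config.genotype,
                )
            )
    cells = assign_regions(cells, config.atlas)
    return BrainDataset(brain_id=brain_id, genotype=config.genotype, cells=cells)


def simulate_brains(config: SyntheticBrainConfig) -> list[BrainDataset]:
    """All ``n_brains`` datasets of a config, brain ids distinct."""
    return [simulate_two_class_brain(config, i) for i in range(config.n_brains)]


# ---------------------------------------------------------------------------
# Serial optical sectioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SerialImagingConfig:
    """Optical sectioning model: plane grid anchored at z=0, spacing Δz."""

    optical_spacing_um: float = 10.0
    cell_radius_um: float = 10.0
    xy_jitter_sd_um: float = 0.0
    detection_prob: float = 1.0

    def __post_init__(self):
        if self.optical_spacing_um <= 0:
            raise ValueError("optical_spacing_um must be > 0")
        if self.cell_radius_um <= 0:
            raise ValueError("cell_radius_um must be > 0")
        if not 0 < self.detection_prob <= 1:
            raise ValueError("detection_prob must be in (0, 1]")
        if self.xy_jitter_sd_um < 0:
            raise ValueError("xy_jitter_sd_um must be >= 0")


def simulate_serial_detections(
    cells: Sequence[CellRecord],
    cfg: SerialImagingConfig,
    seed: int,
) -> list[DetectionEvent]:
    """One detection event per optical plane intersecting each soma.

    A cell at depth z is detected on every plane ``k*Δz`` with
    ``|k*Δz − z| <= cell_radius`` (inclusive), each plane independently kept
    with ``detection_prob``; event xy is the soma xy plus Gaussian jitter.
    The event records its source-cell index as hidden ground truth.
    """
    rng = np.random.default_rng(seed)
    dz = cfg.optical_spacing_um
    r = cfg.cell_radius_um
    events: list[DetectionEvent] = []
    for idx, cell in enumerate(cells):
        z = cell.position.z
        k_lo = int(np.ceil((z - r) / dz - 1e-9))
        k_hi = int(np.floor((z + r) / dz + 1e-9))
        for k in range(k_lo, k_hi + 1):
            if cfg.detection_prob < 1 and rng.random() >= cfg.detection_prob:
                continue
            jitter = (
                rng.normal(0.0, cfg.xy_jitter_sd_um, size=2)
                if cfg.xy_jitter_sd_um > 0
                else np.zeros(2)
            )
            events.append(
                DetectionEvent(
                    x_um=cell.position.x + jitter[0],
                    y_um=cell.position.y + jitter[1],
                    z_plane_um=k * dz,
                    slice_index=k,
                    brain_id=cell.brain_id,
                    source_cell_id=idx,
                )
            )
    return events


# ---------------------------------------------------------------------------
# Migration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMigrationModel:
    """Planted mean direction + vMF concentration for one region."""

    mean_direction: tuple[float, float, float]
    kappa: float
    n_cells: int

    def __post_init__(self):
        norm = float(np.linalg.norm(self.mean_direction))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError("mean_direction must be unit-norm")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass(frozen=True)
class MigrationConfig:
    per_region: Mapping[str, RegionMigrationModel]
    length_mean_um: float = 30.0
    length_sd_um: float = 5.0
    stage: str = "E17.5"
    brain_id: str = "brain00"


def sample_vmf(
    mean_direction: np.ndarray, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n unit vectors from a von Mises–Fisher distribution on S²; κ=0 → uniform."""
    mu = np.asarray(mean_direction, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if kappa == 0:
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    return vonmises_fisher(mu, kappa).rvs(n, random_state=rng)


def simulate_migration(
    cfg: MigrationConfig, atlas: RegionAtlas, seed: int
) -> list[LeadingProcessRecord]:
    """Leading-process records with vMF directions planted per region.

    Somas are uniform inside each region's box; process lengths are
    truncated-normal (resampled until positive).  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    boxes = {b.region_id: b for b in atlas.boxes}
    records: list[LeadingProcessRecord] = []
    for region_id in sorted(cfg.per_region):
        model = cfg.per_region[region_id]
        if region_id not in boxes:
            raise ValueError(f"region {region_id!r} not in atlas")
        box = boxes[region_id]
        lo = np.array(box.min_corner)
        hi = np.array(box.max_corner)
        directions = sample_vmf(
            np.array(model.mean_direction), model.kappa, model.n_cells, rng
        )
        somas = rng.uniform(lo, hi, size=(model.n_cells, 3))
        lengths = rng.normal(cfg.length_mean_um, cfg.length_sd_um, model.n_cells)
        while (lengths <= 0).any():
            bad = lengths <= 0
            lengths[bad] = rng.normal(cfg.length_mean_um, cfg.length_sd_um, bad.sum())
        for soma, d, ln in zip(somas, directions, lengths):
            tip = soma + ln * d
            records.append(
                LeadingProcessRecord(
                    soma=Point3D(*soma),
                    tip=Point3D(*tip),
                    region_id=region_id,
                    stage=cfg.stage,
                    brain_id=cfg.brain_id,
                )
            )
    return records


# ---------------------------------------------------------------------------
# 2D fluorescence-like rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SliceImageConfig:
    size_px: int = 256
    pixel_um: float = 1.0
    psf_sd_px: float = 2.0
    background: float = 10.0
    poisson_noise: bool = False

    def __post_init__(self):
        if self.size_px <= 0:
            raise ValueError("size_px must be > 0")
        if self.pixel_um <= 0 or self.psf_sd_px <= 0:
            raise ValueError("pixel_um and psf_sd_px must be > 0")


def render_synthetic_slice(
    blobs: Sequence[tuple[float, float, float]],
    cfg: SliceImageConfig,
    seed: int = 0,
) -> np.ndarray:
    """Render (x_um, y_um, amplitude) blobs as a 2D Gaussian-spot image.

    image = background + Σ amplitude·exp(−r²/2σ²), optionally Poisson
    sampled.  Blob centres must lie inside the field of view.
    """
    fov = cfg.size_px * cfg.pixel_um
    for x, y, _ in blobs:
        if not (0 <= x < fov and 0 <= y < fov):
            raise ValueError(f"blob at ({x}, {y}) µm outside field of view [0, {fov})")
    yy, xx = np.mgrid[0 : cfg.size_px, 0 : cfg.size_px]
    image = np.full((cfg.size_px, cfg.size_px), float(cfg.background))
    for x_um, y_um, amp in blobs:
        cx = x_um / cfg.pixel_um
        cy = y_um / cfg.pixel_um
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        image += amp * np.exp(-r2 / (2 * cfg.psf_sd_px**2))
    if cfg.poisson_noise:
        rng = np.random.default_rng(seed)
        image = rng.poisson(image).astype(float)
    return image


def save_slice_tiff(image: np.ndarray, path) -> None:
    """Write a rendered slice as a single-channel float32 TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
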