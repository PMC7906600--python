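import numpy as np
import pytest

from thalamap.core import CellRecord, Point3D
from thalamap.detection import correct_axial_oversampling, detect_blobs
from thalamap.orientation import mean_resultant_direction, vectors_of
from thalamap.synthetic import (
    ClassSpatialModel,
    GaussianComponent,
    MigrationConfig,
    RegionMigrationModel,
    SerialImagingConfig,
    SliceImageConfig,
    SyntheticBrainConfig,
    default_atlas,
    default_two_class_config,
    render_synthetic_slice,
    sample_vmf,
    simulate_brains,
    simulate_migration,
    simulate_serial_detections,
    simulate_two_class_brain,
)

from conftest import poisson_disk_points


def _cell(x, y, z, brain="b1"):
    return CellRecord(Point3D(x, y, z), "classA", brain)


class TestBrainGenerator:
    def test_deterministic(self):
        cfg = default_two_class_config(seed=9, n_brains=1, n_cells_per_class=50)
        a = simulate_two_class_brain(cfg, 0)
        b = simulate_two_class_brain(cfg, 0)
        assert a == b

    def test_brain_index_changes_sample(self):
        cfg = default_two_class_config(seed=9, n_brains=2, n_cells_per_class=50)
        assert simulate_two_class_brain(cfg, 0).cells != simulate_two_class_brain(
            cfg, 1
        ).cells

    def test_planted_class_means_recovered(self):
        n = 1000
        cfg = default_two_class_config(seed=5, n_brains=1, n_cells_per_class=n)
        ds = simulate_two_class_brain(cfg, 0)
        for label in ("classA", "classB"):
            model = cfg.class_models[label]
            planted = sum(
                c.weight * c.mean.as_array() for c in model.components
            )
            sample_mean = ds.positions(label).mean(axis=0)
            # mixture SD bounded by component SD + centre spread (< 600 µm)
            tol = 3 * 600 / np.sqrt(n)
            assert np.all(np.abs(sample_mean - planted) < tol)
        # the planted caudal/rostral contrast shows up in z
        assert ds.positions("classA")[:, 2].mean() < ds.positions("classB")[:, 2].mean()

    def test_n_brains_distinct_ids(self):
        cfg = default_two_class_config(seed=1, n_brains=3, n_cells_per_class=10)
        ids = [b.brain_id for b in simulate_brains(cfg)]
        assert len(set(ids)) == 3

    def test_zero_cells_rejected(self, atlas):
        cfg = SyntheticBrainConfig(
            seed=0,
            n_brains=1,
            class_models={
                "classA": ClassSpatialModel(
                    components=(
                        GaussianComponent(Point3D(0, 0, 0), (1, 1, 1), 1.0),
                    ),
                    n_cells=0,
                )
            },
            atlas=atlas,
        )
        with pytest.raises(ValueError, match="zero total cells"):
            simulate_two_class_brain(cfg, 0)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ClassSpatialModel(
                components=(
                    GaussianComponent(Point3D(0, 0, 0), (1, 1, 1), 0.5),
                ),
                n_cells=5,
            )


class TestSerialDetections:
    def test_cell_between_planes(self):
        cfg = SerialImagingConfig()
        events = simulate_serial_detections([_cell(0, 0, 15)], cfg, seed=0)
        assert sorted(e.z_plane_um for e in events) == [10.0, 20.0]

    def test_cell_on_plane_three_events(self):
        cfg = SerialImagingConfig()
        events = simulate_serial_detections([_cell(0, 0, 10)], cfg, seed=0)
        assert sorted(e.z_plane_um for e in events) == [0.0, 10.0, 20.0]

    def test_no_jitter_xy_preserved(self):
        cfg = SerialImagingConfig()
        events = simulate_serial_detections([_cell(3.5, -2.0, 15)], cfg, seed=0)
        assert all(e.x_um == 3.5 and e.y_um == -2.0 for e in events)

    def test_source_cell_recorded(self):
        cfg = SerialImagingConfig()
        cells = [_cell(0, 0, 15), _cell(100, 0, 15)]
        events = simulate_serial_detections(cells, cfg, seed=0)
        assert {e.source_cell_id for e in events} == {0, 1}

    def test_deterministic_given_seed(self):
        cfg = SerialImagingConfig(xy_jitter_sd_um=2.0, detection_prob=0.7)
        cells = [_cell(0, 0, z) for z in range(0, 300, 30)]
        assert simulate_serial_detections(
            cells, cfg, seed=4
        ) == simulate_serial_detections(cells, cfg, seed=4)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            SerialImagingConfig(optical_spacing_um=0)
        with pytest.raises(ValueError):
            SerialImagingConfig(detection_prob=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_dedup_round_trip(self, seed):
        """prob 1 + no jitter + cells > 2r apart → correction inverts exactly."""
        rng = np.random.default_rng(seed)
        cfg = SerialImagingConfig()
        pts = poisson_disk_points(rng, n=40, min_dist=2 * cfg.cell_radius_um)
        cells = [_cell(*p) for p in pts]
        events = simulate_serial_detections(cells, cfg, seed=seed)
        recovered = correct_axial_oversampling(events, cfg.cell_radius_um)
        assert len(recovered) == len(cells)
        # median (member-keeping) mode recovers z to within one plane spacing
        from scipy.spatial import cKDTree

        d, idx = cKDTree(pts[:, :2]).query(recovered[:, :2])
        assert np.all(d < 1e-9)  # xy preserved exactly (no jitter)
        assert np.all(
            np.abs(recovered[:, 2] - pts[idx, 2]) <= cfg.optical_spacing_um + 1e-9
        )
        # averaging mode centres each group: z error bounded by Δz/2
        averaged = correct_axial_oversampling(
            events, cfg.cell_radius_um, mode="mean"
        )
        assert len(averaged) == len(cells)
        d, idx = cKDTree(pts[:, :2]).query(averaged[:, :2])
        assert np.all(d < 1e-9)
        assert np.all(
            np.abs(averaged[:, 2] - pts[idx, 2])
            <= cfg.optical_spacing_um / 2 + 1e-9
        )


class TestMigration:
    def _config(self, kappa, n):
        return MigrationConfig(
            per_region={
                "LGd": RegionMigrationModel(
                    mean_direction=(0.0, 0.0, 1.0), kappa=kappa, n_cells=n
                )
            }
        )

    def test_high_kappa_concentrates(self, atlas):
        records = simulate_migration(self._config(1e4, 200), atlas, seed=1)
        vecs = vectors_of(records)
        cos = vecs[:, 2] / np.linalg.norm(vecs, axis=1)
        assert np.all(np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0)

    def test_kappa_zero_uniform(self, atlas):
        records = simulate_migration(self._config(0.0, 2000), atlas, seed=2)
        _, r = mean_resultant_direction(records)
        assert r < 0.08  # E[R] ~ 1/sqrt(n) for uniform directions

    def test_same_seed_identical(self, atlas):
        cfg = self._config(20, 50)
        assert simulate_migration(cfg, atlas, seed=7) == simulate_migration(
            cfg, atlas, seed=7
        )

    def test_somas_inside_region_box(self, atlas):
        records = simulate_migration(self._config(10, 100), atlas, seed=3)
        box = next(b for b in atlas.boxes if b.region_id == "LGd")
        for r in records:
            assert box.contains(r.soma)

    def test_unit_norm_required(self):
        with pytest.raises(ValueError, match="unit-norm"):
            RegionMigrationModel(mean_direction=(0, 0, 2.0), kappa=1, n_cells=1)

    def test_unknown_region_rejected(self, atlas):
        cfg = MigrationConfig(
            per_region={
                "nope": RegionMigrationModel((0, 0, 1.0), kappa=1, n_cells=1)
            }
        )
        with pytest.raises(ValueError, match="nope"):
            simulate_migration(cfg, atlas, seed=0)

    def test_sample_vmf_mean_direction(self):
        rng = np.random.default_rng(11)
        mu = np.array([0.0, -1.0, 1.0]) / np.sqrt(2)
        draws = sample_vmf(mu, 50.0, 1000, rng)
        mean_dir, _ = mean_resultant_direction(draws)
        assert np.degrees(np.arccos(np.clip(mean_dir @ mu, -1, 1))) < 5.0


class TestRenderSlice:
    def test_no_cells_constant_background(self):
        cfg = SliceImageConfig(size_px=32, background=7.0)
        img = render_synthetic_slice([], cfg)
        assert np.all(img == 7.0)

    def test_single_blob_argmax_at_centre(self):
        cfg = SliceImageConfig(size_px=64, pixel_um=2.0, background=1.0)
        img = render_synthetic_slice([(60.0, 40.0, 100.0)], cfg)
        row, col = np.unravel_index(img.argmax(), img.shape)
        assert (col, row) == (30, 20)  # µm / pixel_um

    def test_detector_recovers_three_blobs(self):
        cfg = SliceImageConfig(
            size_px=128, pixel_um=1.0, psf_sd_px=2.0, background=5.0,
            poisson_noise=True,
        )
        planted = [(20.0, 20.0, 500.0), (64.0, 90.0, 500.0), (100.0, 30.0, 500.0)]
        img = render_synthetic_slice(planted, cfg, seed=8)
        found = detect_blobs(img, threshold=50.0, min_area_px=3, pixel_um=1.0)
        assert len(found) == 3
        for x, y, _ in planted:
            d = np.linalg.norm(found - [x, y], axis=1).min()
            assert d <= 1.0

    def test_out_of_fov_rejected(self):
        cfg = SliceImageConfig(size_px=32, pixel_um=1.0)
        with pytest.raises(ValueError, match="field of view"):
            render_synthetic_slice([(40.0, 0.0, 1.0)], cfg)

    def test_bad_size_rejected(self):
        with pytest.raises(ValueError):
            SliceImageConfig(size_px=0)

    def test_tiff_roundtrip(self, tmp_path):
        import tifffile

        from thalamap.synthetic import save_slice_tiff

        cfg = SliceImageConfig(size_px=16)
        img = render_synthetic_slice([(5.0, 5.0, 30.0)], cfg)
        p = tmp_path / "slice.tif"
        save_slice_tiff(img, p)
        np.testing.assert_allclose(tifffile.imread(p), img, rtol=1e-6)

    def test_noise_deterministic_given_seed(self):
        cfg = SliceImageConfig(size_px=32, poisson_noise=True)
        a = render_synthetic_slice([(10.0, 10.0, 50.0)], cfg, seed=3)
        b = render_synthetic_slice([(10.0, 10.0, 50.0)], cfg, seed=3)
        np.testing.assert_array_equal(a, b)
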