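import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thalamap.core import Point3D
from thalamap.orientation import (
    LeadingProcessRecord,
    angle_between_deg,
    angular_histogram,
    dominant_axis_fractions,
    load_processes,
    mean_resultant_direction,
    polar_histogram,
    process_vector,
    save_processes,
    traceable_fraction,
)
from thalamap.synthetic import (
    MigrationConfig,
    RegionMigrationModel,
    simulate_migration,
)


def _rec(vec, soma=(0.0, 0.0, 0.0), **kw):
    return LeadingProcessRecord(
        soma=Point3D(*soma),
        tip=Point3D(soma[0] + vec[0], soma[1] + vec[1], soma[2] + vec[2]),
        **kw,
    )


class TestProcessVector:
    def test_pure_rostral(self):
        _, theta, _, length = process_vector(_rec((0, 0, 1)))
        assert theta == 0.0 and length == 1.0

    def test_hand_trigonometry(self):
        _, theta, phi, length = process_vector(_rec((1, 1, 0)))
        assert theta == pytest.approx(np.pi / 2)
        assert phi == pytest.approx(np.pi / 4)
        assert length == pytest.approx(np.sqrt(2))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            process_vector(_rec((0, 0, 0), region_id="LGd"))

    finite = st.floats(-100, 100, allow_nan=False)

    @given(finite, finite, finite)
    @settings(max_examples=100, deadline=None)
    def test_spherical_roundtrip(self, x, y, z):
        v = np.array([x, y, z])
        if np.linalg.norm(v) < 1e-6:
            return
        _, theta, phi, length = process_vector(_rec((x, y, z)))
        rebuilt = length * np.array(
            [
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.cos(theta),
            ]
        )
        np.testing.assert_allclose(rebuilt, v, atol=1e-9 * max(1.0, length))


class TestAngularHistogram:
    def test_identical_vectors_single_bin(self):
        records = [_rec((1, 1, 1)) for _ in range(7)]
        hist = angular_histogram(records, 6, 8)
        assert hist.counts.sum() == 7
        assert (hist.frequencies > 0).sum() == 1
        assert hist.frequencies.max() == 1.0

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        records = [_rec(v) for v in rng.normal(size=(100, 3))]
        hist = angular_histogram(records)
        assert hist.frequencies.sum() == pytest.approx(1.0)
        assert hist.counts.sum() == 100

    def test_uniform_sphere_theta_marginal(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(20000, 3))
        records = [_rec(tuple(x)) for x in v]
        hist = angular_histogram(records, n_theta_bins=6, n_phi_bins=4)
        marginal = hist.frequencies.sum(axis=1)
        edges = hist.theta_edges
        expected = (np.cos(edges[:-1]) - np.cos(edges[1:])) / 2  # solid angle
        np.testing.assert_allclose(marginal, expected, atol=0.02)

    def test_boundary_angles_in_last_bin(self):
        # theta = pi (pure caudal) must land in the final theta bin
        hist = angular_histogram([_rec((0, 0, -1)), _rec((0, 0, -1))], 4, 4)
        assert hist.counts[-1].sum() == 2

    def test_errors(self):
        with pytest.raises(ValueError):
            angular_histogram([], 4, 4)
        with pytest.raises(ValueError):
            angular_histogram([_rec((1, 0, 0))], 1, 4)


class TestDominantAxisFractions:
    def test_all_rostral(self):
        fr = dominant_axis_fractions([_rec((0, 0, 1))] * 3)
        assert fr.fractions["caudo-rostral"] == 1.0
        assert fr.fractions["rostro-caudal"] == 0.0

    def test_two_thirds_one_third(self):
        fr = dominant_axis_fractions(
            [_rec((0, 0, 1)), _rec((0, 0, 1)), _rec((0, 0, -1))]
        )
        assert fr.fractions["caudo-rostral"] == pytest.approx(2 / 3)
        assert fr.fractions["rostro-caudal"] == pytest.approx(1 / 3)

    def test_magnitude_invariant(self):
        rng = np.random.default_rng(2)
        vecs = rng.normal(size=(50, 3))
        a = dominant_axis_fractions([_rec(tuple(v)) for v in vecs])
        b = dominant_axis_fractions([_rec(tuple(7.3 * v)) for v in vecs])
        assert a.fractions == b.fractions

    def test_fractions_sum_to_one_per_axis(self):
        vecs = [(1, 0, 1), (0, -1, 0), (-2, 3, 0), (0, 0, -1)]
        fr = dominant_axis_fractions([_rec(v) for v in vecs])
        for axis, pos, neg in (
            ("x", "medio-lateral", "latero-medial"),
            ("y", "ventro-dorsal", "dorso-ventral"),
            ("z", "caudo-rostral", "rostro-caudal"),
        ):
            total = (
                fr.fractions[pos] + fr.fractions[neg] + fr.zero_fractions[axis]
            )
            assert total == pytest.approx(1.0)

    def test_planted_vmf_dominant_direction(self, atlas):
        direction = np.array([0.0, -1.0, 1.0]) / np.sqrt(2)
        cfg = MigrationConfig(
            per_region={
                "LGd": RegionMigrationModel(tuple(direction), kappa=20, n_cells=500)
            }
        )
        records = simulate_migration(cfg, atlas, seed=3)
        fr = dominant_axis_fractions(records)
        assert fr.fractions["dorso-ventral"] > 0.6
        assert fr.fractions["caudo-rostral"] > 0.6

    def test_hemisphere_marginals_match_fractions(self):
        """Two-route check: summing histogram hemispheres == sign fractions."""
        rng = np.random.default_rng(4)
        vecs = rng.normal(size=(400, 3))
        records = [_rec(tuple(v)) for v in vecs]
        fr = dominant_axis_fractions(records)
        hist = angular_histogram(records, n_theta_bins=18, n_phi_bins=36)
        # caudo-rostral ↔ theta < pi/2 (bins 0..8 of 18)
        rostral = hist.frequencies[:9, :].sum()
        assert rostral == pytest.approx(fr.fractions["caudo-rostral"], abs=1e-12)
        # ventro-dorsal ↔ phi in (0, pi) (bins 18..35 of 36)
        dorsal = hist.frequencies[:, 18:].sum()
        assert dorsal == pytest.approx(fr.fractions["ventro-dorsal"], abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dominant_axis_fractions([])


class TestPolarHistogram:
    def test_single_direction_bin(self):
        out = polar_histogram([_rec((0, 1, 0))] * 4, plane="xy", n_bins=8)
        assert out.counts.sum() == 4
        centre_angles = (out.bin_edges[:-1] + out.bin_edges[1:]) / 2
        hot = centre_angles[out.counts.argmax()]
        assert abs(hot - np.pi / 2) < np.pi / 4

    def test_zero_projection_excluded(self):
        out = polar_histogram(
            [_rec((0, 0, 1)), _rec((1, 0, 0))], plane="xy", n_bins=8
        )
        assert out.n_excluded == 1
        assert out.counts.sum() == 1

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError, match="projection"):
            polar_histogram([_rec((0, 0, 1))], plane="xy")

    def test_mirror_symmetry(self):
        vecs = [(1, 2, 0), (1, -2, 0), (-3, 1, 0), (-3, -1, 0)]
        out = polar_histogram([_rec(v) for v in vecs], plane="xy", n_bins=8)
        np.testing.assert_array_equal(out.counts, out.counts[::-1])

    def test_bad_plane(self):
        with pytest.raises(ValueError):
            polar_histogram([_rec((1, 0, 0))], plane="ab")


class TestTraceableFraction:
    def test_forty_four_percent(self):
        records = [
            _rec((0, 0, 1), stage="E17.5", traceable=(i < 44)) for i in range(100)
        ]
        assert traceable_fraction(records)["E17.5"] == pytest.approx(0.44)

    def test_none_traceable(self):
        records = [_rec((0, 0, 1), stage="P0.5", traceable=False)] * 5
        assert traceable_fraction(records)["P0.5"] == 0.0

    def test_all_traceable(self):
        records = [_rec((0, 0, 1), stage="P1.5", traceable=True)] * 5
        assert traceable_fraction(records)["P1.5"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            traceable_fraction([])


class TestMeanResultant:
    def test_high_kappa_recovery(self, atlas):
        direction = np.array([0.0, -1.0, 1.0]) / np.sqrt(2)
        cfg = MigrationConfig(
            per_region={
                "LGd": RegionMigrationModel(tuple(direction), kappa=50, n_cells=1000)
            }
        )
        records = simulate_migration(cfg, atlas, seed=6)
        mean_dir, r = mean_resultant_direction(records)
        assert angle_between_deg(mean_dir, direction) < 5.0
        assert r > 0.9


class TestProcessIO:
    def test_roundtrip(self, tmp_path, atlas):
        cfg = MigrationConfig(
            per_region={"VP": RegionMigrationModel((0, 0, 1.0), kappa=5, n_cells=20)}
        )
        records = simulate_migration(cfg, atlas, seed=0)
        p = tmp_path / "proc.csv"
        save_processes(records, p)
        back = load_processes(p)
        assert len(back) == len(records)
        np.testing.assert_allclose(
            [r.soma.x for r in back], [r.soma.x for r in records]
        )
        assert all(r.region_id == "VP" and r.traceable for r in back)
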