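"""Centerline extraction, partitioning, diameters and curvature fitting."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from aortiq import morphometry as M
from aortiq.errors import DegenerateGeometryError, TopologyError
from aortiq.phantoms import make_cylinder_phantom, make_elliptic_cylinder_mask
from tests.conftest import BULGE_APEX_DIAMETER_MM, BULGE_CENTER_MM


def ellipse_mean_chord_oracle(a: float, b: float, n_angles: int = 10_000) -> float:
    """Dense-angular numerical mean of the ellipse's full central chords."""
    theta = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    return float(np.mean(2.0 / np.sqrt((np.cos(theta) / a) ** 2 + (np.sin(theta) / b) ** 2)))


class TestExtractCenterline:
    def test_cylinder_centerline_collinear_with_axis(self):
        mask, truth = make_cylinder_phantom(tube_radius_mm=15.0, length_mm=80.0)
        cl = M.extract_centerline(mask, endpoints_mm=truth.endpoints_mm)
        radial_dev = np.hypot(cl.points_mm[:, 0], cl.points_mm[:, 1])
        assert radial_dev.max() < mask.spacing_mm[0] / 2.0
        assert cl.length_mm == pytest.approx(80.0, abs=2.0)

    def test_candycane_close_to_ground_truth(self, cane, cane_centerline):
        _, _, truth = cane
        d, _ = cKDTree(truth.centerline_points_mm).query(cane_centerline.points_mm)
        assert d.mean() < 1.0  # < 1 voxel mean deviation

    def test_resampling_spacing_bound(self, cane_centerline):
        assert np.all(np.diff(cane_centerline.arc_length_mm) <= 1.0 + 1e-9)

    def test_two_components_rejected(self):
        m1, _ = make_cylinder_phantom(tube_radius_mm=6.0, length_mm=20.0)
        vox = np.zeros((m1.voxels.shape[0], m1.voxels.shape[1], 50), dtype=bool)
        vox[:, :, :21] = m1.voxels
        vox[:, :, 29:] = m1.voxels
        mask = M.LumenMask(vox, m1.spacing_mm, m1.origin_mm)
        with pytest.raises(TopologyError, match="components"):
            M.extract_centerline(mask)

    def test_blob_rejected(self):
        x, y, z = np.indices((31, 31, 31)).astype(float) - 15.0
        ball = x**2 + y**2 + z**2 <= 13.0**2
        mask = M.LumenMask(ball, np.ones(3), np.zeros(3))
        with pytest.raises(TopologyError, match="elongated"):
            M.extract_centerline(mask)

    def test_loop_rejected(self):
        # a full torus has a handle: Euler number 0
        idx = np.indices((61, 61, 21)).astype(float)
        x = idx[0] - 30.0
        y = idx[1] - 30.0
        z = idx[2] - 10.0
        torus = (np.sqrt(x**2 + y**2) - 20.0) ** 2 + z**2 <= 6.0**2
        mask = M.LumenMask(torus, np.ones(3), np.zeros(3))
        with pytest.raises(TopologyError, match="loop"):
            M.extract_centerline(mask)


class TestPartitionSegments:
    def test_fractions_on_400mm(self, straight_centerline):
        part = M.partition_segments(
            straight_centerline, (0.2, 0.35, 0.8), as_fractions=True
        )
        assert part.boundaries_mm == pytest.approx((80.0, 140.0, 320.0))

    def test_phantom_joint_landmarks_recover_s1_length(self, cane, cane_centerline):
        _, _, truth = cane
        part = M.partition_segments(cane_centerline, truth.segment_boundaries_mm)
        lo, hi = part.extent("S1")
        assert hi - lo == pytest.approx(truth.true_segment_lengths_mm["S1"], rel=0.02)

    def test_plane_landmark(self, straight_centerline):
        part = M.partition_segments(
            straight_centerline,
            [
                {"point": [0, 0, 100.0], "normal": [0, 0, 1.0]},
                {"point": [0, 0, 200.0], "normal": [0, 0, 1.0]},
                {"point": [0, 0, 300.0], "normal": [0, 0, 1.0]},
            ],
        )
        assert part.boundaries_mm == pytest.approx((100.0, 200.0, 300.0))

    def test_unordered_landmarks_rejected(self, straight_centerline):
        with pytest.raises(ValueError, match="ordered"):
            M.partition_segments(straight_centerline, (140.0, 80.0, 320.0))

    def test_landmark_outside_extent_rejected(self, straight_centerline):
        with pytest.raises(ValueError, match="outside"):
            M.partition_segments(straight_centerline, (80.0, 140.0, 500.0))


class TestCrossSections:
    def test_cylinder_diameter_within_half_voxel(self):
        mask, truth = make_cylinder_phantom(tube_radius_mm=20.0, length_mm=60.0)
        cl = M.extract_centerline(mask, endpoints_mm=truth.endpoints_mm)
        profiles = M.build_cross_sections(mask, cl)
        interior = [
            p for p in profiles if 2.0 <= p.station_arc_length_mm <= cl.length_mm - 2.0
        ]
        diam = np.array([p.mean_diameter_mm for p in interior])
        assert np.all(np.abs(diam - 40.0) < 0.5 * mask.spacing_mm[0])

    @pytest.mark.parametrize("a,b", [(25.0, 15.0), (20.0, 20.0)])
    def test_elliptic_diameter_matches_dense_angular_oracle(self, a, b):
        mask = make_elliptic_cylinder_mask(a, b, length_mm=24.0)
        z = np.arange(4.0, 21.0)
        cl = M.Centerline(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
        profiles = M.build_cross_sections(mask, cl, step_mm=4.0)
        oracle = ellipse_mean_chord_oracle(a, b)
        measured = np.mean([p.mean_diameter_mm for p in profiles])
        assert measured == pytest.approx(oracle, rel=0.01)

    def test_refinement_does_not_increase_diameter_error(self):
        oracle = ellipse_mean_chord_oracle(25.0, 15.0)
        errs = []
        for vox in (1.0, 0.5):
            mask = make_elliptic_cylinder_mask(25.0, 15.0, length_mm=10.0, voxel_size_mm=vox)
            z = np.array([3.0, 5.0, 7.0])
            cl = M.Centerline(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
            profiles = M.build_cross_sections(mask, cl, step_mm=2.0)
            errs.append(abs(np.mean([p.mean_diameter_mm for p in profiles]) - oracle))
        assert errs[1] <= errs[0] + 1e-6

    def test_bulge_apex_located(self, cane, cane_centerline):
        _, mask, _ = cane
        profiles = M.build_cross_sections(mask, cane_centerline)
        means = np.array([p.mean_diameter_mm for p in profiles])
        stations = np.array([p.station_arc_length_mm for p in profiles])
        apex = stations[np.argmax(means)]
        assert apex == pytest.approx(BULGE_CENTER_MM, abs=2.0)


class TestSegmentMorphometry:
    def test_cylinder_split_reports_same_diameter(self):
        mask, truth = make_cylinder_phantom(tube_radius_mm=20.0, length_mm=60.0)
        cl = M.extract_centerline(mask, endpoints_mm=truth.endpoints_mm)
        profiles = M.build_cross_sections(mask, cl)
        part = M.partition_segments(cl, (0.25, 0.5, 0.75), as_fractions=True)
        morph = M.segment_morphometry(profiles, part)
        for m in morph:
            assert m.max_mean_diameter_mm == pytest.approx(40.0, abs=0.5)

    def test_bulged_phantom_s1_max_diameter(self, cane, cane_centerline):
        _, mask, truth = cane
        profiles = M.build_cross_sections(mask, cane_centerline)
        part = M.partition_segments(cane_centerline, truth.segment_boundaries_mm)
        morph = {m.segment_id: m for m in M.segment_morphometry(profiles, part)}
        assert morph["S1"].max_mean_diameter_mm == pytest.approx(
            BULGE_APEX_DIAMETER_MM, abs=1.0
        )
        assert morph["S1"].station_of_max_mm == pytest.approx(BULGE_CENTER_MM, abs=2.0)

    def test_partition_beyond_coverage_rejected(self, straight_centerline):
        profiles = [
            M.CrossSectionProfile(s, np.array([0, 0, 1.0]), np.full(4, 30.0))
            for s in np.arange(0.0, 100.0)
        ]
        part = M.SegmentPartition((80.0, 140.0, 320.0), 400.0)
        with pytest.raises(ValueError, match="cover"):
            M.segment_morphometry(profiles, part)


class TestCurvatureFit:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_arc_any_orientation(self, seed):
        rng = np.random.default_rng(seed)
        theta = np.linspace(0.2, 1.9, 80)
        pts = 45.0 * np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        rot = Rotation.random(random_state=seed).as_matrix()
        pts = pts @ rot.T + rng.normal(0, 30, size=3)
        fit = M.fit_curvature_radius(M.Centerline(pts))
        assert fit.radius_mm == pytest.approx(45.0, rel=1e-6)
        assert fit.rms_residual_mm < 1e-9

    def test_noisy_phantom_recovery_within_2pct(self, noisy_cane):
        spec, mask, truth = noisy_cane
        cl = M.extract_centerline(mask, endpoints_mm=truth.endpoints_mm)
        part = M.partition_segments(cl, truth.segment_boundaries_mm)
        fit = M.fit_curvature_radius(cl.restrict(*part.extent("S1")))
        assert fit.radius_mm == pytest.approx(truth.true_curvature_radius_mm, rel=0.02)

    def test_straight_line_rejected(self):
        z = np.linspace(0.0, 40.0, 20)
        cl = M.Centerline(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
        with pytest.raises(DegenerateGeometryError, match="near-straight"):
            M.fit_curvature_radius(cl)

    def test_too_short_or_too_few_points_rejected(self):
        theta = np.linspace(0.0, 0.1, 30)
        pts = 45.0 * np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        with pytest.raises(DegenerateGeometryError, match="10 mm"):
            M.fit_curvature_radius(M.Centerline(pts))
        with pytest.raises(DegenerateGeometryError, match="5 centerline points"):
            M.fit_curvature_radius(
                M.Centerline(np.column_stack([np.cos([0, 0.5, 1.0]), np.sin([0, 0.5, 1.0]), [0, 0, 0]]) * 45)
            )


class TestRigidInvariance:
    def test_rotation_invariance_of_measurements(self, noisy_cane):
        """A 90-degree rotation of the volume changes lengths/curvature by < 1%."""
        spec, mask, truth = noisy_cane

        cl = M.extract_centerline(mask, endpoints_mm=truth.endpoints_mm)
        part = M.partition_segments(cl, truth.segment_boundaries_mm)
        fit = M.fit_curvature_radius(cl.restrict(*part.extent("S1")))

        rot_vox = np.rot90(mask.voxels, k=1, axes=(0, 1))
        n1 = mask.voxels.shape[1]
        mask_r = M.LumenMask(rot_vox, mask.spacing_mm, np.zeros(3))

        def rotate_world(p):
            idx = (np.asarray(p) - mask.origin_mm) / mask.spacing_mm
            # np.rot90(axes=(0,1)): new[i, j, k] = old[j, n1-1-i, k]
            new_idx = np.array([n1 - 1 - idx[1], idx[0], idx[2]])
            return new_idx * mask.spacing_mm

        eps_r = [rotate_world(p) for p in truth.endpoints_mm]
        cl_r = M.extract_centerline(mask_r, endpoints_mm=eps_r)
        part_r = M.partition_segments(cl_r, truth.segment_boundaries_mm)
        fit_r = M.fit_curvature_radius(cl_r.restrict(*part_r.extent("S1")))

        assert cl_r.length_mm == pytest.approx(cl.length_mm, rel=0.01)
        assert fit_r.radius_mm == pytest.approx(fit.radius_mm, rel=0.01)
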