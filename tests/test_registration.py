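"""NCC metric, sparse sampling, landmark/affine/B-spline registration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cochmetric.errors import (
    DegenerateLandmarksError,
    DegenerateMetricError,
    InsufficientOverlapError,
)
from cochmetric.imaging import FiducialSet, RegionOfInterest, Volume3D
from cochmetric.registration import (
    RegistrationConfig,
    evaluate_metric,
    ncc,
    register_affine,
    register_bspline,
    register_landmarks,
    sample_points,
)
from cochmetric.transforms import AffineTransform, TransformChain

from conftest import FAST_CONFIG


class TestNCC:
    def test_self_correlation(self):
        x = np.random.Generator(np.random.Philox(0)).normal(size=100)
        assert ncc(x, x) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 1000),
        a=st.floats(0.01, 50.0),
        b=st.floats(-100.0, 100.0),
    )
    def test_positive_affine_intensity_invariance(self, seed, a, b):
        x = np.random.Generator(np.random.Philox(seed)).normal(size=64)
        assert ncc(x, a * x + b) == pytest.approx(1.0, abs=1e-9)
        assert ncc(x, -a * x + b) == pytest.approx(-1.0, abs=1e-9)

    def test_independent_vectors_nearly_uncorrelated(self):
        rng = np.random.Generator(np.random.Philox(1))
        x, y = rng.normal(size=(2, 100_000))
        assert abs(ncc(x, y)) < 0.02  # ~3/sqrt(n) sampling bound

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateMetricError):
            ncc(np.ones(10), np.arange(10.0))
        with pytest.raises(DegenerateMetricError):
            ncc(np.array([1.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            ncc(np.arange(5.0), np.arange(6.0))


class TestSamplePoints:
    VOL = Volume3D(np.zeros((20, 20, 20)), (1, 1, 1), (0, 0, 0))

    def test_full_fraction_returns_all_centers(self):
        roi = RegionOfInterest((-0.5, -0.5, -0.5), (4.5, 4.5, 4.5))
        pts = sample_points(self.VOL, roi, 1.0, seed=0)
        assert pts.shape == (125, 3)

    def test_deterministic_sample_size_and_repeatability(self):
        roi = self.VOL.extent_roi()
        a = sample_points(self.VOL, roi, 0.01, seed=5)
        b = sample_points(self.VOL, roi, 0.01, seed=5)
        c = sample_points(self.VOL, roi, 0.01, seed=6)
        assert a.shape == (round(0.01 * 8000), 3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_sample_mean_near_roi_center(self):
        big = Volume3D(np.zeros((40, 40, 40)), (1, 1, 1), (0, 0, 0))
        roi = big.extent_roi()
        pts = sample_points(big, roi, 0.05, seed=2)
        n = pts.shape[0]
        sigma = (39.0) / np.sqrt(12)  # uniform over the center range
        assert np.max(np.abs(pts.mean(axis=0) - roi.center)) < 3 * sigma / np.sqrt(n)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            sample_points(self.VOL, self.VOL.extent_roi(), 0.001, seed=0)


class TestEvaluateMetric:
    @pytest.fixture()
    def textured(self):
        rng = np.random.Generator(np.random.Philox(9))
        return Volume3D(rng.normal(size=(24, 24, 24)), (1, 1, 1), (0, 0, 0))

    def test_identity_self_metric(self, textured):
        pts = sample_points(textured, textured.extent_roi(), 0.05, seed=1)
        value = evaluate_metric(textured, textured, TransformChain(), pts)
        assert value == pytest.approx(1.0, abs=1e-12)

    def test_intensity_rescaling_invariance(self, textured):
        scaled = Volume3D(2.0 * textured.voxels + 100.0, textured.spacing,
                          textured.origin)
        pts = sample_points(textured, textured.extent_roi(), 0.05, seed=1)
        assert evaluate_metric(textured, scaled, TransformChain(), pts) == \
            pytest.approx(1.0, abs=1e-12)

    def test_known_translation_recovers_unity(self, textured):
        shift = np.array([3.0, 0.0, 0.0])  # whole voxels: interpolation exact
        moved = Volume3D(textured.voxels, textured.spacing,
                         textured.origin + shift)
        t = AffineTransform(np.eye(3), shift)
        inner = RegionOfInterest(textured.extent_roi().lower + 4,
                                 textured.extent_roi().upper - 4)
        pts = sample_points(textured, inner, 0.1, seed=3)
        assert evaluate_metric(textured, moved, t, pts) > 1.0 - 1e-3

    def test_insufficient_overlap(self, textured):
        t = AffineTransform(np.eye(3), (1000.0, 0.0, 0.0))
        pts = sample_points(textured, textured.extent_roi(), 0.05, seed=1)
        with pytest.raises(InsufficientOverlapError):
            evaluate_metric(textured, textured, t, pts)


def _fidset(points):
    return FiducialSet({f"p{i}": p for i, p in enumerate(points)})


class TestLandmarkRegistration:
    POINTS = np.array(
        [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 8.0, 0.0], [0.0, 0.0, 6.0]]
    )

    def test_identity_for_identical_sets(self):
        fid = _fidset(self.POINTS)
        t = register_landmarks(fid, fid)
        assert np.allclose(t.matrix, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-12)
        assert t.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        shift = np.array([5.0, -2.0, 1.0])
        moved = self.POINTS @ rot.T + shift
        t = register_landmarks(_fidset(self.POINTS), _fidset(moved))
        assert t.rigid and t.n_dof == 6
        assert np.max(np.abs(t.apply_points(self.POINTS) - moved)) < 1e-9

    def test_uniform_scaling_leaves_residual(self):
        t = register_landmarks(_fidset(self.POINTS), _fidset(1.2 * self.POINTS))
        assert t.residual_rms > 0.1  # 6 DOF cannot represent scaling

    def test_matches_small_angle_grid_search(self):
        """Closed form beats (to 1e-6 mm) an exhaustive z-rotation +
        centroid-translation grid search on a 4-point toy set built from a
        pure z-rotation, where the search space contains the optimum."""
        from scipy.spatial.transform import Rotation

        angle_true = np.deg2rad(4.0)
        rot = Rotation.from_euler("z", angle_true).as_matrix()
        target = self.POINTS @ rot.T + np.array([1.0, 2.0, -1.0])
        t = register_landmarks(_fidset(self.POINTS), _fidset(target))
        closed_rms = t.residual_rms

        a_c = self.POINTS - self.POINTS.mean(axis=0)
        b_c = target - target.mean(axis=0)
        best = np.inf
        for theta in np.linspace(-np.deg2rad(10), np.deg2rad(10), 20001):
            r = Rotation.from_euler("z", theta).as_matrix()
            rms = np.sqrt(np.mean(np.sum((a_c @ r.T - b_c) ** 2, axis=1)))
            best = min(best, rms)
        assert closed_rms <= best + 1e-6

    def test_degenerate_configurations(self):
        line = _fidset(np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]))
        with pytest.raises(DegenerateLandmarksError, match="collinear"):
            register_landmarks(line, line)
        a = _fidset(self.POINTS)
        b = FiducialSet({"p0": self.POINTS[0], "other": self.POINTS[1]})
        with pytest.raises(DegenerateLandmarksError, match="missing"):
            register_landmarks(a, b)


@pytest.fixture(scope="module")
def phantom_volume(small_phantom):
    return small_phantom[0]


class TestAffineStage:
    def test_self_registration(self, phantom_volume):
        """Registering a volume to an exact copy of itself from identity
        stays within 0.1 voxel of the identity map, NCC >= 0.999."""
        vol = phantom_volume
        t = register_affine(vol, vol, TransformChain(), FAST_CONFIG)
        pts = vol.voxel_centers()[:: 1311]
        drift = np.max(np.linalg.norm(t.apply_points(pts) - pts, axis=1))
        assert drift <= 0.1 * float(np.max(vol.spacing))
        assert t.final_ncc >= 0.999

    def test_metric_trace_monotone(self, phantom_volume):
        """Best-so-far NCC is non-decreasing over iterations within every
        multiresolution level (each level has its own smoothed objective)."""
        vol = phantom_volume
        init = TransformChain([AffineTransform(np.eye(3), (0.4, -0.3, 0.2))])
        t = register_affine(vol, vol, init, FAST_CONFIG)
        assert len(t.metric_traces) == FAST_CONFIG.multiresolution_levels
        for trace in t.metric_traces:
            assert np.all(np.diff(np.array(trace)) >= -1e-12)

    def test_recovers_known_affine(self, small_bundle):
        """Known scale/rotation/translation deformation: the composed
        recovered mapping places fiducials within half a coarse voxel."""
        from conftest import all_fiducials, deformed_target

        bundle, _ = small_bundle
        target, mapped, _, chain = deformed_target(
            bundle, seed=11, target_spacing=(0.45,) * 3, target_shape=(40,) * 3,
            max_displacement_mm=0.0,  # affine-only ground truth
        )
        lm = mapped.subset(["apex", "modiolus", "round_window", "oval_window"])
        rigid = register_landmarks(bundle.init_landmarks, lm)
        init = TransformChain([rigid])
        aff = register_affine(bundle.volume, target, init, FAST_CONFIG)
        full = init.extended(aff)
        got = full.apply_points(bundle.aval_fiducials.as_array())
        true = chain.apply_points(bundle.aval_fiducials.as_array())
        assert np.max(np.linalg.norm(got - true, axis=1)) <= 0.5 * 0.45


class TestBSplineStage:
    def test_null_deformation_on_identical_images(self, phantom_volume):
        vol = phantom_volume
        init = TransformChain([AffineTransform.identity(rigid=True)])
        ffd = register_bspline(vol, vol, init, FAST_CONFIG)
        norms = np.linalg.norm(ffd.displacements, axis=-1)
        assert np.max(norms) <= 0.1

    def test_improves_over_affine_on_warped_target(self, small_bundle):
        from conftest import deformed_target

        bundle, _ = small_bundle
        target, mapped, _, _ = deformed_target(
            bundle, seed=21, target_spacing=(0.45,) * 3, target_shape=(40,) * 3,
            scale_range=(1.0, 1.0), rotation_range_deg=0.0,
            translation_range_mm=0.0, max_displacement_mm=1.5,
        )
        lm = mapped.subset(["apex", "modiolus", "round_window", "oval_window"])
        init = TransformChain([register_landmarks(bundle.init_landmarks, lm)])
        aff = register_affine(bundle.volume, target, init, FAST_CONFIG)
        chain = init.extended(aff)
        pts = sample_points(bundle.volume, bundle.volume.extent_roi(), 1.0,
                            seed=0)[:: 37]
        ncc_affine = evaluate_metric(bundle.volume, target, chain, pts)
        ffd = register_bspline(bundle.volume, target, chain, FAST_CONFIG,
                               points=pts)
        ncc_ffd = evaluate_metric(bundle.volume, target, chain.extended(ffd), pts)
        assert ncc_ffd > ncc_affine

    def test_grid_accounting(self, phantom_volume):
        vol = phantom_volume
        init = TransformChain([AffineTransform.identity(rigid=True)])
        ffd = register_bspline(vol, vol, init, FAST_CONFIG)
        assert ffd.grid_shape == (4, 4, 4)
        assert ffd.n_control_points == 64
        assert ffd.n_parameters == 192

    def test_requires_init(self, phantom_volume):
        from cochmetric.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            register_bspline(phantom_volume, phantom_volume, TransformChain())

    def test_displacement_cap_respected(self, small_bundle):
        from conftest import deformed_target

        bundle, _ = small_bundle
        target, mapped, _, _ = deformed_target(
            bundle, seed=31, target_spacing=(0.45,) * 3, target_shape=(40,) * 3
        )
        lm = mapped.subset(["apex", "modiolus", "round_window", "oval_window"])
        init = TransformChain([register_landmarks(bundle.init_landmarks, lm)])
        aff = register_affine(bundle.volume, target, init, FAST_CONFIG)
        ffd = register_bspline(bundle.volume, target, init.extended(aff),
                               FAST_CONFIG)
        cap = FAST_CONFIG.displacement_cap_factor * ffd.grid_spacing
        assert np.all(np.abs(ffd.displacements) <= cap + 1e-12)


class TestDeterminism:
    def test_identical_inputs_and_seed_bitwise_identical(self, small_bundle):
        from conftest import deformed_target

        bundle, _ = small_bundle
        target, mapped, _, _ = deformed_target(
            bundle, seed=41, target_spacing=(0.45,) * 3, target_shape=(40,) * 3
        )
        lm = mapped.subset(["apex", "modiolus", "round_window", "oval_window"])
        init = TransformChain([register_landmarks(bundle.init_landmarks, lm)])
        a1 = register_affine(bundle.volume, target, init, FAST_CONFIG)
        a2 = register_affine(bundle.volume, target, init, FAST_CONFIG)
        assert np.array_equal(a1.matrix, a2.matrix)
        assert np.array_equal(a1.translation, a2.translation)
        f1 = register_bspline(bundle.volume, target, init.extended(a1), FAST_CONFIG)
        f2 = register_bspline(bundle.volume, target, init.extended(a2), FAST_CONFIG)
        assert np.array_equal(f1.displacements, f2.displacements)
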