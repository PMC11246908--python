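import math

import numpy as np
import pytest

from lumbometry import geometry, phantom
from lumbometry.errors import DegenerateGeometryError, MissingKeypointError
from lumbometry.geometry import (
    KeyPointSet, Line2D, Point2D, angle_between_lines, compute_all_parameters,
    endplate_line, intervertebral_space_angle, lumbar_lordosis,
    percent_spondylolisthesis, posterior_edge_line, sacral_horizontal_angle,
)

from conftest import canonical_keypoints


class TestEndplateLine:
    def test_horizontal(self):
        line = endplate_line(Point2D(0, 0), Point2D(10, 0))
        assert abs(line.direction[1]) == 0.0
        assert abs(line.direction[0]) == 1.0

    def test_vertical(self):
        line = endplate_line(Point2D(0, 0), Point2D(0, 5))
        assert line.direction[0] == 0.0
        assert abs(line.direction[1]) == 1.0

    def test_oblique_direction(self):
        # direction proportional to (3, 2)/sqrt(13), oriented toward anterior
        line = endplate_line(Point2D(1, 1), Point2D(4, 3), anterior_side="right")
        expected = (3 / math.sqrt(13), 2 / math.sqrt(13))
        assert line.direction == pytest.approx(expected)

    def test_orientation_toward_anterior(self):
        left = endplate_line(Point2D(1, 1), Point2D(4, 3), anterior_side="left")
        assert left.direction[0] <= 0

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            endplate_line(Point2D(3, 3), Point2D(3, 3))


class TestAngleBetweenLines:
    def test_parallel_zero(self):
        l1 = Line2D(Point2D(0, 0), (1.0, 0.0))
        l2 = Line2D(Point2D(0, 5), (-1.0, 0.0))
        assert angle_between_lines(l1, l2) == 0.0

    def test_perpendicular(self):
        l1 = Line2D(Point2D(0, 0), (1.0, 0.0))
        l2 = Line2D(Point2D(0, 0), (0.0, 1.0))
        assert angle_between_lines(l1, l2) == pytest.approx(90.0)

    def test_forty_five(self):
        l1 = Line2D(Point2D(0, 0), (1.0, 0.0))
        s = 1 / math.sqrt(2)
        l2 = Line2D(Point2D(0, 0), (s, s))
        assert angle_between_lines(l1, l2) == pytest.approx(45.0)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = rng.uniform(0, 2 * np.pi, 2)
            l1 = Line2D(Point2D(0, 0), (math.cos(a), math.sin(a)))
            l2 = Line2D(Point2D(0, 0), (math.cos(b), math.sin(b)))
            v, w = angle_between_lines(l1, l2), angle_between_lines(l2, l1)
            assert v == w
            assert 0.0 <= v <= 90.0


class TestLumbarLordosis:
    def test_parallel_endplates_zero(self):
        assert lumbar_lordosis(canonical_keypoints()) == pytest.approx(0.0)

    def test_forty_degrees(self):
        # L1 horizontal; S1 endplate at 40 deg to horizontal.
        dy = 40.0 * math.tan(math.radians(40.0))
        kps = canonical_keypoints(S1SA=(20.0, 150.0 + dy), S1SP=(60.0, 150.0))
        assert lumbar_lordosis(kps) == pytest.approx(40.0)

    def test_missing_landmark_named(self):
        kps = canonical_keypoints()
        del kps.points["L1SP"]
        with pytest.raises(MissingKeypointError, match="L1SP"):
            lumbar_lordosis(kps)


class TestSacralHorizontalAngle:
    def test_horizontal_endplate(self):
        kps = canonical_keypoints(S1SA=(10.0, 50.0), S1SP=(40.0, 50.0))
        assert sacral_horizontal_angle(kps) == pytest.approx(0.0)

    def test_forty_five(self):
        kps = canonical_keypoints(S1SA=(0.0, 0.0), S1SP=(10.0, 10.0))
        assert sacral_horizontal_angle(kps) == pytest.approx(45.0)

    def test_missing_landmark(self):
        kps = canonical_keypoints()
        del kps.points["S1SA"]
        with pytest.raises(MissingKeypointError):
            sacral_horizontal_angle(kps)


class TestIntervertebralSpaceAngle:
    def test_parallel_zero(self):
        assert intervertebral_space_angle(
            canonical_keypoints(), "L4L5"
        ) == pytest.approx(0.0)

    def test_lordotic_wedge_positive_ten(self):
        # Lower endplate horizontal; upper inferior endplate rises 10 deg
        # toward the anterior (left) side -> +10.
        rise = 40.0 * math.tan(math.radians(10.0))
        kps = canonical_keypoints(L4IA=(20.0, 100.0 - rise), L4IP=(60.0, 100.0))
        assert intervertebral_space_angle(kps, "L4L5") == pytest.approx(10.0)

    def test_kyphotic_wedge_negative(self):
        drop = 40.0 * math.tan(math.radians(7.0))
        kps = canonical_keypoints(L5IA=(20.0, 140.0 + drop), L5IP=(60.0, 140.0))
        assert intervertebral_space_angle(kps, "L5S1") == pytest.approx(-7.0)

    def test_bad_segment(self):
        with pytest.raises(ValueError):
            intervertebral_space_angle(canonical_keypoints(), "L3L4")


class TestPosteriorEdgeLine:
    def test_l5_vertical(self):
        kps = canonical_keypoints(L5SP=(50.0, 10.0), L5IP=(50.0, 40.0))
        line = posterior_edge_line(kps, "L5")
        assert abs(line.direction[0]) == pytest.approx(0.0)

    def test_s1_perpendicular_to_horizontal_endplate(self):
        kps = canonical_keypoints()  # S1 endplate horizontal
        line = posterior_edge_line(kps, "S1")
        assert abs(line.direction[0]) == pytest.approx(0.0, abs=1e-12)
        assert line.anchor == kps["S1SP"]

    def test_l4_parallel_to_l5(self):
        kps = canonical_keypoints(L5SP=(58.0, 112.0), L5IP=(62.0, 140.0))
        l5 = posterior_edge_line(kps, "L5")
        l4 = posterior_edge_line(kps, "L4")
        assert l4.direction == l5.direction
        assert l4.anchor == kps["L4IP"]


class TestPercentSpondylolisthesis:
    def test_collinear_posterior_lines_zero(self):
        assert percent_spondylolisthesis(
            canonical_keypoints(), "L4L5"
        ) == pytest.approx(0.0)

    def test_hand_built_slip(self):
        # N = 5 px anterior slip of L4 over L5; M = 40 px -> +12.5 %.
        kps = canonical_keypoints(L4IA=(15.0, 100.0), L4IP=(55.0, 100.0))
        assert percent_spondylolisthesis(kps, "L4L5") == pytest.approx(12.5)

    def test_posterior_slip_negative(self):
        kps = canonical_keypoints(L5SA=(24.0, 110.0), L5SP=(64.0, 110.0),
                                  L5IA=(24.0, 140.0), L5IP=(64.0, 140.0))
        assert percent_spondylolisthesis(kps, "L5S1") == pytest.approx(-10.0)

    def test_zero_m_degenerate(self):
        kps = canonical_keypoints()
        kps.points["S1SA"] = kps.points["S1SP"]
        with pytest.raises(DegenerateGeometryError):
            percent_spondylolisthesis(kps, "L5S1")


def _transform_kps(kps: KeyPointSet, fn, anterior_side=None) -> KeyPointSet:
    return KeyPointSet(
        points={k: Point2D(*fn(p)) for k, p in kps.points.items()},
        pixel_spacing=kps.pixel_spacing,
        anterior_side=anterior_side or kps.anterior_side,
    )


@pytest.fixture(scope="module")
def phantom_kps_sets():
    rng = np.random.default_rng(123)
    out = []
    for _ in range(25):
        spec = phantom.sample_spec(rng=rng)
        out.append((phantom.solve_keypoints(spec), spec.targets()))
    return out


class TestComputeAllParameters:
    def test_phantom_closure(self, phantom_kps_sets):
        for kps, truth in phantom_kps_sets:
            got = compute_all_parameters(kps)
            for name in geometry.PARAMETER_NAMES:
                assert getattr(got, name) == pytest.approx(
                    getattr(truth, name), abs=1e-6
                ), name

    def test_translation_invariance(self, phantom_kps_sets):
        kps, _ = phantom_kps_sets[0]
        base = compute_all_parameters(kps)
        moved = _transform_kps(kps, lambda p: (p.x + 31.7, p.y - 12.3))
        got = compute_all_parameters(moved)
        for name in geometry.PARAMETER_NAMES:
            assert getattr(got, name) == pytest.approx(
                getattr(base, name), abs=1e-9
            )

    def test_uniform_scale_invariance(self, phantom_kps_sets):
        kps, _ = phantom_kps_sets[1]
        base = compute_all_parameters(kps)
        scaled = _transform_kps(kps, lambda p: (p.x * 2.5, p.y * 2.5))
        got = compute_all_parameters(scaled)
        for name in geometry.PARAMETER_NAMES:
            assert getattr(got, name) == pytest.approx(
                getattr(base, name), abs=1e-9
            )

    def test_mirror_invariance(self, phantom_kps_sets):
        width = 500.0
        for kps, _ in phantom_kps_sets[:5]:
            base = compute_all_parameters(kps)
            flipped_side = "right" if kps.anterior_side == "left" else "left"
            mirrored = _transform_kps(
                kps, lambda p: (width - p.x, p.y), anterior_side=flipped_side
            )
            got = compute_all_parameters(mirrored)
            for name in geometry.PARAMETER_NAMES:
                assert getattr(got, name) == pytest.approx(
                    getattr(base, name), abs=1e-9
                )

    def test_rotation_covariance(self, phantom_kps_sets):
        # Rotation changes SHA but leaves LL / ISA / PLS untouched.
        kps, _ = phantom_kps_sets[2]
        base = compute_all_parameters(kps)
        theta = math.radians(7.0)
        c, s = math.cos(theta), math.sin(theta)
        rotated = _transform_kps(
            kps, lambda p: (c * p.x - s * p.y, s * p.x + c * p.y)
        )
        got = compute_all_parameters(rotated)
        for name in ("LL", "ISA_L4L5", "ISA_L5S1", "PLS_L4L5", "PLS_L5S1"):
            assert getattr(got, name) == pytest.approx(
                getattr(base, name), abs=1e-9
            )
        assert abs(got.SHA - base.SHA) > 1.0

    def test_missing_landmark_propagates(self):
        kps = canonical_keypoints()
        del kps.points["L4IA"]
        with pytest.raises(MissingKeypointError):
            compute_all_parameters(kps)


class TestPropertyBased:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    finite = st.floats(-1e3, 1e3).filter(lambda v: abs(v) > 1e-6)

    @given(dx=finite, dy=finite)
    @settings(max_examples=50, deadline=None)
    def test_translation_invariance_random_offsets(self, dx, dy):
        kps = canonical_keypoints(L4IA=(15.0, 98.0), S1SA=(22.0, 163.0))
        base = compute_all_parameters(kps)
        moved = _transform_kps(kps, lambda p: (p.x + dx, p.y + dy))
        got = compute_all_parameters(moved)
        for name in geometry.PARAMETER_NAMES:
            assert getattr(got, name) == pytest.approx(
                getattr(base, name), abs=1e-7
            )

    @given(a=st.floats(0, 2 * math.pi), b=st.floats(0, 2 * math.pi))
    @settings(max_examples=100, deadline=None)
    def test_angle_between_lines_properties(self, a, b):
        l1 = Line2D(Point2D(0, 0), (math.cos(a), math.sin(a)))
        l2 = Line2D(Point2D(1, 1), (math.cos(b), math.sin(b)))
        angle = angle_between_lines(l1, l2)
        assert 0.0 <= angle <= 90.0
        assert angle == angle_between_lines(l2, l1)
        flipped = Line2D(Point2D(0, 0), (-math.cos(a), -math.sin(a)))
        assert angle == pytest.approx(angle_between_lines(flipped, l2), abs=1e-9)


class TestKeyPointSetValidation:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            KeyPointSet(points={"T12SA": Point2D(0, 0)})

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            KeyPointSet(points={"L1SA": Point2D(float("nan"), 0)})

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            KeyPointSet(points={}, pixel_spacing=(0.0, 0.2))
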