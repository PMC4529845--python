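import math

import numpy as np
import pytest

from transsylvian import (
    ApproachVector,
    HemisphereSide,
    Point3,
    SphenoidRidgeLine,
    compute_approach_angles,
    compute_chpc_angles,
    compute_sphenoid_angle,
    compute_target_point,
    parallelism_offset,
)
from transsylvian.coordinate_frames import CHPC_OBLIQUITY_DEG, chpc_rotation
from transsylvian.errors import (
    CoronalMismatchError,
    DegenerateLineError,
    DegenerateProjectionError,
)


def pt(x, y, z, frame="acpc"):
    return Point3(x, y, z, frame)


def vector(origin, disp, side="right"):
    """ApproachVector with a right-normalized displacement de-mirrored for side."""
    o = np.asarray(origin, float)
    d = np.asarray(disp, float)
    if side == "left":
        o = o * np.array([-1, 1, 1])
        d = d * np.array([-1, 1, 1])
    return ApproachVector(
        origin=pt(*o), target=pt(*(o + d)), side=HemisphereSide(side)
    )


class TestTargetPoint:
    def test_midpoint_arithmetic(self):
        out = compute_target_point(pt(-22, -6, -16), pt(-38, -6, -12))
        assert (out.x, out.y, out.z) == (-30, -6, -14)

    def test_degenerate_identical_points(self):
        p = pt(5, -6, -14)
        out = compute_target_point(p, p)
        assert out == p

    def test_different_coronal_slices_rejected(self):
        with pytest.raises(CoronalMismatchError):
            compute_target_point(pt(-22, -6, -16), pt(-38, -8, -12))

    def test_tolerance_boundary_is_half_millimetre(self):
        out = compute_target_point(pt(0, -6.0, 0), pt(10, -6.5, 0))
        assert out.y == -6.25


class TestApproachAngles:
    def test_pure_lateral_displacement_is_zero_zero(self):
        a = compute_approach_angles(vector([33, 6, -14], [10, 0, 0]))
        assert a.theta_a == 0.0 and a.theta_c == 0.0

    def test_equal_posterior_and_lateral_gives_45(self):
        a = compute_approach_angles(vector([33, 6, -14], [10, -10, 0]))
        assert math.isclose(a.theta_a, 45.0, abs_tol=1e-12)
        assert a.theta_c == 0.0

    def test_study_mean_displacement_reproduces_printed_means(self):
        # displacement with 8 mm adjacent side, 10.4 mm posterior, 2.32 mm
        # inferior -> the cohort's mean axial/coronal angles
        a = compute_approach_angles(vector([33, 6, -14], [8, -10.4, -2.32]))
        assert math.isclose(a.theta_a, 52.4, abs_tol=0.05)
        assert math.isclose(a.theta_c, 16.2, abs_tol=0.05)

    def test_matches_arctangent_oracle(self, rng):
        for _ in range(50):
            d = rng.uniform([-20, -25, -25], [-0.5, 25, 25])
            d[0] = -d[0]  # ensure positive lateral component
            a = compute_approach_angles(vector([30, 5, -15], d))
            assert math.isclose(
                a.theta_a, math.degrees(math.atan2(-d[1], d[0])), abs_tol=1e-9
            )
            assert math.isclose(
                a.theta_c, math.degrees(math.atan2(-d[2], d[0])), abs_tol=1e-9
            )

    def test_translation_invariance(self, rng):
        d = [8, -10.4, -2.32]
        a0 = compute_approach_angles(vector([33, 6, -14], d))
        shift = rng.uniform(-40, 40, 3)
        a1 = compute_approach_angles(vector(np.array([33, 6, -14]) + shift, d))
        assert math.isclose(a0.theta_a, a1.theta_a, abs_tol=1e-9)
        assert math.isclose(a0.theta_c, a1.theta_c, abs_tol=1e-9)

    def test_left_configuration_equals_mirrored_right(self, rng):
        for _ in range(20):
            o = rng.uniform([20, -10, -25], [45, 15, -5])
            d = rng.uniform([3, -20, -15], [15, 5, 10])
            r = compute_approach_angles(vector(o, d, "right"))
            l = compute_approach_angles(vector(o, d, "left"))
            assert r.theta_a == l.theta_a
            assert r.theta_c == l.theta_c

    def test_tiny_lateral_component_rejected(self):
        with pytest.raises(DegenerateProjectionError):
            compute_approach_angles(vector([33, 6, -14], [0.05, -10, -3]))

    def test_medial_overshoot_warns_but_computes(self):
        with pytest.warns(UserWarning):
            a = compute_approach_angles(vector([33, 6, -14], [-5, -10, 0]))
        assert a.theta_a > 90


class TestSphenoidAngle:
    def test_line_parallel_to_x_axis(self):
        line = SphenoidRidgeLine(pt(50, 5, 0), pt(30, 5, 0), HemisphereSide.RIGHT)
        assert compute_sphenoid_angle(line) == 0.0

    def test_equal_medial_and_posterior_components_give_45(self):
        line = SphenoidRidgeLine(pt(50, 5, -5), pt(30, 25, -5), HemisphereSide.RIGHT)
        # outer->inner (-20, +20): folded to (+20, -20): posterior-positive 45
        assert math.isclose(compute_sphenoid_angle(line), 45.0, abs_tol=1e-12)

    def test_matches_slope_oracle(self, rng):
        for _ in range(50):
            outer = rng.uniform([30, -20, -20], [60, 20, 0])
            delta = rng.uniform([-40, -40, -5], [40, 40, 5])
            if np.hypot(delta[0], delta[1]) < 2:
                continue
            line = SphenoidRidgeLine(
                pt(*outer), pt(*(outer + delta)), HemisphereSide.RIGHT
            )
            got = compute_sphenoid_angle(line)
            dx, dy = delta[0], delta[1]
            if dx < 0:
                dx, dy = -dx, -dy
            expected = 90.0 if dx == 0 else math.degrees(math.atan2(-dy, dx))
            assert math.isclose(got, expected, abs_tol=1e-9)
            assert -90 < got <= 90

    def test_direction_independence(self):
        a = SphenoidRidgeLine(pt(50, 5, 0), pt(30, 25, 0), HemisphereSide.RIGHT)
        b = SphenoidRidgeLine(pt(30, 25, 0), pt(50, 5, 0), HemisphereSide.RIGHT)
        assert compute_sphenoid_angle(a) == compute_sphenoid_angle(b)

    def test_vertical_line_rejected(self):
        line = SphenoidRidgeLine(pt(40, 5, -20), pt(40.1, 5.1, 20), HemisphereSide.RIGHT)
        with pytest.raises(DegenerateLineError):
            compute_sphenoid_angle(line)


class TestChpcAngles:
    def test_x_axis_displacement_invariant(self):
        v = vector([33, 6, -14], [10, 0, 0])
        acpc = compute_approach_angles(v)
        chpc = compute_chpc_angles(v)
        assert chpc.theta_a == acpc.theta_a == 0.0
        assert chpc.frame == "chpc"

    def test_axial_plane_displacement_couples_into_coronal(self):
        v = vector([33, 6, -14], [8, -10.4, 0])
        d = chpc_rotation() @ np.array([8, -10.4, 0.0])
        expected = compute_chpc_angles(v)
        assert math.isclose(
            expected.theta_c, math.degrees(math.atan2(-d[2], d[0])), abs_tol=1e-9
        )
        phi = math.radians(-CHPC_OBLIQUITY_DEG)
        assert math.isclose(d[2], math.sin(phi) * -10.4, abs_tol=1e-12)

    def test_transfer_preserves_vector_norm(self):
        d = np.array([8.0, -10.4, -2.32])
        assert math.isclose(
            np.linalg.norm(chpc_rotation() @ d), np.linalg.norm(d), abs_tol=1e-12
        )

    def test_zero_obliquity_reduces_to_acpc_angles(self, rng):
        for _ in range(10):
            o = rng.uniform([20, -10, -25], [45, 15, -5])
            d = rng.uniform([3, -20, -15], [15, 5, 10])
            v = vector(o, d)
            assert compute_chpc_angles(v, obliquity_deg=0.0) == compute_approach_angles(v)


class TestParallelismOffset:
    def test_printed_mean_angles_offset(self):
        assert math.isclose(parallelism_offset(52.4, 49.7), 2.7, abs_tol=1e-12)

    def test_equal_angles_offset_zero(self):
        assert parallelism_offset(49.7, 49.7) == 0.0

    def test_signed(self):
        assert parallelism_offset(40.0, 52.0) == -12.0
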