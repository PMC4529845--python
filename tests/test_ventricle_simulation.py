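import math

import numpy as np
import pytest

from transsylvian import (
    ApproachVector,
    HemisphereSide,
    HornProfile,
    MaskVolume,
    Point3,
    StandardVector,
    cast_ray,
    compute_approach_angles,
    direction_from_angles,
    make_inferior_horn_mask,
    simulate_cohort,
)
from transsylvian.errors import InvalidProfileError, MissingLandmarkError
from transsylvian import GeneratorConfig, generate_tle_cohort


class TestHornMask:
    def test_straight_tube_volume_matches_analytic_cylinder(self):
        L, r = 40.0, 3.0
        profile = HornProfile(
            centerline=((0, 0, 0), (L, 0, 0)), radius=r, name="control"
        )
        mask = make_inferior_horn_mask(profile, voxel_size=1.0)
        expected = math.pi * r * r * L
        assert abs(mask.foreground_count() - expected) / expected < 0.10

    def test_subvoxel_radius_still_traces_centerline(self):
        profile = HornProfile(centerline=((0, 0, 0), (20, 0, 0)), radius=0.4)
        mask = make_inferior_horn_mask(profile, voxel_size=1.0)
        assert mask.foreground_count() >= 20

    def test_left_mask_is_voxelwise_mirror_of_right(self):
        profile = HornProfile(
            centerline=((30, -5, -15), (35, -15, -12), (38, -25, -8)), radius=3.0
        )
        right = make_inferior_horn_mask(profile, 1.0, HemisphereSide.RIGHT)
        left = make_inferior_horn_mask(profile, 1.0, HemisphereSide.LEFT)
        assert np.array_equal(left.voxels, right.voxels[::-1, :, :])
        # a foreground voxel's world position mirrors in x
        ijk = np.argwhere(right.voxels == 1)[0]
        mirrored = np.array([right.voxels.shape[0] - 1 - ijk[0], ijk[1], ijk[2]])
        wr = right.voxel_to_world(ijk)
        wl = left.voxel_to_world(mirrored)
        assert np.allclose(wl, [-wr[0], wr[1], wr[2]], atol=1e-9)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(InvalidProfileError):
            HornProfile(centerline=((0, 0, 0),), radius=3.0)
        with pytest.raises(InvalidProfileError):
            HornProfile(centerline=((0, 0, 0), (1, 0, 0)), radius=-1.0)
        with pytest.raises(InvalidProfileError):
            make_inferior_horn_mask(
                HornProfile(centerline=((0, 0, 0), (10, 0, 0))), voxel_size=5.0
            )


class TestDirectionFromAngles:
    def test_zero_angles_point_along_x(self):
        u = direction_from_angles(StandardVector(0.0, 0.0), HemisphereSide.RIGHT)
        assert np.allclose(u, [1, 0, 0], atol=1e-12)

    def test_45_degree_axial_geometry(self):
        u = direction_from_angles(StandardVector(45.0, 0.0), HemisphereSide.RIGHT)
        assert math.isclose(-u[1], u[0], abs_tol=1e-12)
        assert u[2] == 0.0
        assert math.isclose(np.linalg.norm(u), 1.0, abs_tol=1e-12)

    def test_left_side_flips_lateral_component(self):
        r = direction_from_angles(StandardVector(52.4, 16.2), "right")
        l = direction_from_angles(StandardVector(52.4, 16.2), "left")
        assert np.allclose(l, [-r[0], r[1], r[2]], atol=1e-15)

    def test_round_trip_through_angle_measurement(self, rng):
        for _ in range(25):
            ta, tc = rng.uniform(-80, 80, 2)
            side = "right" if rng.random() < 0.5 else "left"
            u = direction_from_angles(StandardVector(float(ta), float(tc)), side)
            origin = np.array([33.0, 6.0, -14.0])
            if side == "left":
                origin[0] = -origin[0]
            v = ApproachVector(
                origin=Point3.from_array(origin, "acpc"),
                target=Point3.from_array(origin + 20 * u, "acpc"),
                side=HemisphereSide(side),
            )
            angles = compute_approach_angles(v)
            assert math.isclose(angles.theta_a, ta, abs_tol=1e-9)
            assert math.isclose(angles.theta_c, tc, abs_tol=1e-9)

    def test_angles_at_or_beyond_90_rejected(self):
        with pytest.raises(ValueError):
            direction_from_angles(StandardVector(95.0, 0.0), "right")


def box_mask(lo, hi, shape=(40, 40, 40)):
    vox = np.zeros(shape, dtype=np.uint8)
    vox[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]] = 1
    return MaskVolume(vox, np.eye(4), frame="acpc")


class TestCastRay:
    def test_origin_inside_mask(self):
        mask = box_mask((0, 0, 0), (40, 40, 40))
        res = cast_ray(mask, Point3(5, 5, 5, "acpc"), [1, 0, 0])
        assert res.entered and res.entry_distance == 0.0

    def test_ray_pointing_away_misses(self):
        mask = box_mask((20, 20, 20), (30, 30, 30))
        res = cast_ray(mask, Point3(10, 10, 10, "acpc"), [-1, 0, 0])
        assert not res.entered and res.entry_distance is None

    @pytest.mark.parametrize("axis", [0, 1, 2])
    @pytest.mark.parametrize("sign", [1, -1])
    def test_axis_aligned_entry_matches_voxel_traversal_oracle(self, rng, axis, sign):
        lo = rng.integers(8, 15, 3)
        hi = lo + rng.integers(5, 12, 3)
        mask = box_mask(lo, hi)
        direction = np.zeros(3)
        direction[axis] = sign
        start = np.array([20.0, 20.0, 20.0])
        start[axis] = 2.0 if sign == 1 else 37.0
        res = cast_ray(mask, Point3.from_array(start, "acpc"), direction, step=0.25)

        # oracle: walk voxel indices one by one along the axis
        expected_entered = False
        expected_dist = None
        idx = start.astype(int)
        for k in range(40):
            probe = idx.copy()
            probe[axis] = int(start[axis]) + sign * k
            if (probe < 0).any() or (probe >= 40).any():
                break
            if mask.voxels[tuple(probe)] == 1:
                expected_entered = True
                expected_dist = abs(probe[axis] - start[axis])
                break
        assert res.entered == expected_entered
        if expected_entered:
            # nearest-voxel sampling can fire half a voxel early
            assert abs(res.entry_distance - expected_dist) <= 0.5 + 0.25

    def test_step_refinement_never_unenters(self, rng):
        mask = box_mask((15, 10, 12), (25, 30, 28))
        for _ in range(10):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            origin = Point3.from_array(rng.uniform(2, 8, 3), "acpc")
            coarse = cast_ray(mask, origin, u, step=0.5)
            fine = cast_ray(mask, origin, u, step=0.25)
            if coarse.entered:
                assert fine.entered

    def test_non_unit_direction_rejected(self):
        mask = box_mask((0, 0, 0), (5, 5, 5))
        with pytest.raises(ValueError):
            cast_ray(mask, Point3(0, 0, 0, "acpc"), [1, 1, 0])


class TestSimulateCohort:
    def test_empty_cohort_gives_empty_results(self):
        assert simulate_cohort([], StandardVector()) == []

    def test_missing_limen_rejected(self):
        pairs = generate_tle_cohort(GeneratorConfig(n_tle=1, seed=5))
        del pairs[0][0].entries["limen_insulae"]
        with pytest.raises(MissingLandmarkError):
            simulate_cohort(pairs, StandardVector())

    def test_vector_rotated_away_misses_all(self):
        pairs = generate_tle_cohort(GeneratorConfig(n_tle=3, seed=5))
        # anterior-superior instead of posterior-inferior: points away from horn
        away = StandardVector(theta_a=-45.0, theta_c=-75.0)
        results = simulate_cohort(pairs, away)
        assert sum(r.entered for r in results) == 0

    def test_mirror_symmetry_of_entry(self):
        """A mirrored subject with a mirrored mask reproduces the right-sided
        entry result, entry distance included."""
        profile = HornProfile(
            centerline=((38, -3, -18), (41, -12, -16), (43, -22, -10)), radius=3.0
        )
        vec = StandardVector(52.4, 16.2)
        origin_r = Point3(33.0, 6.0, -14.0, "acpc")
        origin_l = Point3(-33.0, 6.0, -14.0, "acpc")
        mask_r = make_inferior_horn_mask(profile, 1.0, "right")
        mask_l = make_inferior_horn_mask(profile, 1.0, "left")
        res_r = cast_ray(mask_r, origin_r, direction_from_angles(vec, "right"))
        res_l = cast_ray(mask_l, origin_l, direction_from_angles(vec, "left"))
        assert res_r.entered == res_l.entered
        if res_r.entered:
            assert res_r.entry_distance == res_l.entry_distance
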