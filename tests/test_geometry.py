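"""Plane construction: closed-form fits against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from couinaud import (
    DegenerateGeometryError,
    LandmarkSet,
    build_planes,
    fit_axis_plane,
    ivc_axis_of,
    signed_distance,
)
from couinaud.geometry import OrientedPlane

from _oracles import plane_objective, random_rigid, theta_grid_plane

Z_AXIS = (np.zeros(3), np.array([0.0, 0.0, 1.0]))


class TestIvcAxis:
    @pytest.mark.parametrize("sup, expected", [
        ((0, 0, 100), (0, 0, 1)),
        ((0, 3, 4), (0, 0.6, 0.8)),  # 3-4-5 triangle
    ])
    def test_direction(self, canonical_landmarks, sup, expected):
        pts = {n: p.tolist() for n, p in canonical_landmarks.points.items()}
        pts["ivc_inferior"] = [0, 0, 0]
        pts["ivc_superior"] = list(sup)
        point, direction = ivc_axis_of(LandmarkSet(points=pts))
        np.testing.assert_allclose(point, [0, 0, 0])
        np.testing.assert_allclose(direction, expected, atol=1e-12)

    def test_coincident_points_rejected(self, canonical_landmarks):
        pts = {n: p.tolist() for n, p in canonical_landmarks.points.items()}
        pts["ivc_superior"] = pts["ivc_inferior"]
        with pytest.raises(DegenerateGeometryError):
            LandmarkSet(points=pts)


class TestFitAxisPlane:
    def test_exact_fit_two_coplanar_targets(self):
        plane = fit_axis_plane(Z_AXIS, [(0, 10, 90), (0, 50, 10)],
                               orient_toward=(40, 10, 80))
        np.testing.assert_allclose(np.abs(plane.normal), [1, 0, 0],
                                   atol=1e-12)
        assert signed_distance(plane, (40, 10, 80)) > 0

    def test_single_target_worked_example(self):
        # normal = normalize(z x (40,10,80)) = (-0.2425, 0.9701, 0)
        plane = fit_axis_plane(Z_AXIS, [(40, 10, 80)],
                               orient_toward=(15, 50, 20))
        np.testing.assert_allclose(
            plane.normal, [-0.24253563, 0.97014250, 0.0], atol=1e-7)
        assert signed_distance(plane, (15, 50, 20)) == pytest.approx(
            44.87, abs=0.01)
        # the target lies on the plane
        assert abs(signed_distance(plane, (40, 10, 80))) < 1e-9

    def test_symmetric_targets_recover_symmetry_plane(self):
        plane = fit_axis_plane(Z_AXIS, [(10, 20, 50), (-10, 20, 50)],
                               orient_toward=(50, 0, 0))
        np.testing.assert_allclose(np.abs(plane.normal), [1, 0, 0],
                                   atol=1e-9)
        n, obj, _ = theta_grid_plane(*Z_AXIS, [(10, 20, 50), (-10, 20, 50)])
        assert plane_objective(plane, [(10, 20, 50), (-10, 20, 50)]) \
            <= obj + 1e-9

    def test_dominates_theta_grid_on_random_configs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            m = rng.integers(1, 5)
            targets = rng.uniform(-80, 80, size=(m, 3))
            orient = rng.uniform(-80, 80, size=3)
            axis_p = rng.uniform(-20, 20, size=3)
            axis_d = rng.normal(size=3)
            try:
                plane = fit_axis_plane((axis_p, axis_d), targets,
                                       orient_toward=orient)
            except DegenerateGeometryError:
                continue
            _, best, _ = theta_grid_plane(axis_p, axis_d, targets)
            assert plane_objective(plane, targets) <= best + 1e-9

    def test_targets_on_axis_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_axis_plane(Z_AXIS, [(0, 0, 10), (0, 0, 50)],
                           orient_toward=(1, 0, 0))

    def test_orient_point_on_plane_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_axis_plane(Z_AXIS, [(10, 0, 0)], orient_toward=(0, 0, 30))


class TestBuildPlanes:
    def test_canonical_phantom_geometry(self, canonical_planes):
        p = canonical_planes
        # MHV and GB both at x=0 -> main plane is x=0, right positive
        np.testing.assert_allclose(p.main_plane.normal, [1, 0, 0],
                                   atol=1e-12)
        # portal planes perpendicular to the axis at z = 45 / z = 50
        np.testing.assert_allclose(p.right_portal_plane.normal, [0, 0, 1])
        np.testing.assert_allclose(p.right_portal_plane.point, [30, 20, 45])
        np.testing.assert_allclose(p.left_portal_plane.point, [-20, 15, 50])
        # left plane normal: flip of normalize(z x UF) so MHV is positive
        np.testing.assert_allclose(
            p.left_plane.normal, [0.91036648, 0.41380294, 0], atol=1e-7)
        assert signed_distance(p.left_plane, (0, 10, 90)) == pytest.approx(
            4.14, abs=0.01)

    def test_rhv_on_axis_degenerate(self, canonical_landmarks):
        pts = {n: p.tolist() for n, p in canonical_landmarks.points.items()}
        pts["right_hepatic_vein"] = [0, 0, 80]
        with pytest.raises(DegenerateGeometryError):
            build_planes(LandmarkSet(points=pts))

    def test_nonpositive_caudate_radius_rejected(self, canonical_landmarks):
        with pytest.raises(ValueError):
            build_planes(canonical_landmarks, caudate_radius_mm=0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_rigid_equivariance_of_signed_distances(
            self, canonical_landmarks, seed):
        """One rigid transform of all landmarks transforms every plane
        consistently: signed distances to transformed probes are preserved."""
        rng = np.random.default_rng(seed)
        R, t = random_rigid(rng)
        planes = build_planes(canonical_landmarks)
        planes_t = build_planes(canonical_landmarks.transformed(R, t))
        probes = rng.uniform(-120, 120, size=(10, 3))
        for attr in ("main_plane", "right_plane", "left_plane",
                     "right_portal_plane", "left_portal_plane"):
            a = getattr(planes, attr)
            b = getattr(planes_t, attr)
            for probe in probes:
                assert signed_distance(b, R @ probe + t) == pytest.approx(
                    signed_distance(a, probe), abs=1e-9)


class TestSignedDistance:
    def test_basic_cases(self):
        plane = OrientedPlane(point=(0, 0, 0), normal=(1, 0, 0))
        assert signed_distance(plane, (40, 30, 60)) == pytest.approx(40.0)
        assert signed_distance(plane, (0, 5, -3)) == 0.0

    def test_defining_landmark_is_on_portal_plane(self, canonical_planes):
        assert signed_distance(canonical_planes.right_portal_plane,
                               (30, 20, 45)) == 0.0

    def test_planeset_audit_serializes(self, canonical_planes):
        import json
        doc = json.loads(json.dumps(canonical_planes.to_dict()))
        assert doc["caudate_radius_mm"] == 30.0
        assert set(doc["main_plane"]) == {"name", "point", "normal"}
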