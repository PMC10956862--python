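"""Geometry tests for the Cobb-angle construction."""

import numpy as np
import pytest

from spinelcm.cobb import (
    StraightSpineError,
    chord_intersections,
    classify_scoliosis,
    cobb_from_construction,
    curve_endpoints,
    find_apex,
    foot_of_perpendicular,
    measure_cobb,
    perpendicular_intersection,
)


def arc_curve(phi_deg, n=1001, radius=100.0, center=(0.0, 0.0), rot_deg=0.0):
    """Circular-arc curve samples (row, col), central angle phi, apex included."""
    phi = np.radians(phi_deg)
    psi = np.linspace(-phi / 2, phi / 2, n if n % 2 else n + 1)
    pts = np.column_stack(
        [center[0] + radius * np.sin(psi), center[1] - radius * np.cos(psi)]
    )
    if rot_deg:
        a = np.radians(rot_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        pts = pts @ R.T
    return pts


class TestEndpointsAndChord:
    def test_endpoints_are_first_and_last(self):
        curve = np.column_stack([np.arange(10, 201), np.full(191, 50.0)])
        U, L = curve_endpoints(curve)
        assert U[0] == 10 and L[0] == 200

    def test_three_point_curve(self):
        curve = np.array([[0, 5.0], [1, 6.0], [2, 5.0]])
        U, L = curve_endpoints(curve)
        assert np.array_equal(U, [0, 5]) and np.array_equal(L, [2, 5])

    def test_unsorted_rows_rejected(self):
        with pytest.raises(ValueError):
            curve_endpoints(np.array([[2, 0.0], [1, 0.0], [3, 0.0]]))

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            curve_endpoints(np.array([[0, 0.0], [1, 1.0]]))

    def test_c_shape_has_no_interior_crossing(self):
        M, N, interior = chord_intersections(arc_curve(40))
        assert interior == []
        assert M[0] < N[0]

    def test_s_shape_reports_interior_crossing(self):
        r = np.arange(0, 201, dtype=float)
        col = 10 * np.sin(2 * np.pi * r / 200)  # crosses chord mid-way
        _, _, interior = chord_intersections(np.column_stack([r, col]))
        assert len(interior) == 1


class TestApex:
    def test_symmetric_arc_apex_at_middle(self):
        curve = arc_curve(40, n=501)
        M, N, _ = chord_intersections(curve)
        C = find_apex(curve, M, N)
        assert C[0] == pytest.approx(0.0, abs=1e-9)

    def test_sinusoid_apex_matches_analytic(self):
        r = np.arange(10, 201, dtype=float)
        col = 120 - 20 * np.sin(np.pi * (r - 10) / 190)
        curve = np.column_stack([r, col])
        M, N, _ = chord_intersections(curve)
        for rule in ("max_dev", "min_x"):
            C = find_apex(curve, M, N, rule=rule)
            assert np.allclose(C, [105.0, 100.0])

    def test_straight_curve_has_no_apex(self):
        curve = np.column_stack([np.arange(3.0), np.zeros(3)])
        with pytest.raises(StraightSpineError):
            find_apex(curve, curve[0], curve[-1])


class TestPerpendicularIntersection:
    def test_worked_coordinates(self):
        O = perpendicular_intersection((0, 0), (10, 0), (5, -2))
        assert np.allclose(O, [5.0, 12.5])

    def test_unit_circle_O_is_apex_antipode(self):
        for h in (10.0, 30.0, 60.0):
            curve = arc_curve(2 * h, n=2001, radius=1.0)
            M, N, _ = chord_intersections(curve)
            C = find_apex(curve, M, N)
            O = perpendicular_intersection(M, N, C)
            assert np.allclose(O, [0.0, 1.0], atol=1e-6)  # antipode of (0, -1)

    def test_collinear_raises(self):
        with pytest.raises(StraightSpineError):
            perpendicular_intersection((0, 0), (10, 0), (5, 0))


class TestAngleConventions:
    def test_worked_case_both_conventions(self):
        from spinelcm.cobb import CobbConstruction

        M, N, C = np.array([0.0, 0.0]), np.array([10.0, 0.0]), np.array([5.0, -2.0])
        O = perpendicular_intersection(M, N, C)
        P = foot_of_perpendicular(O, M, N)
        assert np.allclose(P, [5.0, 0.0])
        cons = CobbConstruction(U=M, L=N, M=M, N=N, C=C, O=O, P=P, theta_deg=0.0)
        assert cobb_from_construction(cons, "mon") == pytest.approx(43.60, abs=0.005)
        assert cobb_from_construction(cons, "eq5_printed") == pytest.approx(136.40, abs=0.005)

    @pytest.mark.parametrize("phi", [5.0, 15.0, 40.0, 60.0, 90.0])
    def test_circular_arc_identity(self, phi):
        """mon-convention angle of a circular arc equals half its central angle."""
        res = measure_cobb(arc_curve(phi, n=4001))
        assert res.angle_deg == pytest.approx(phi / 2, abs=1e-6)

    def test_conventions_sum_to_180(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            phi = rng.uniform(5, 100)
            curve = arc_curve(phi, n=301)
            # asymmetric perturbation so the construction is not symmetric
            curve[:, 1] += 0.3 * np.sin(np.linspace(0, 2.3, len(curve)))
            res_m = measure_cobb(curve, convention="mon")
            res_e = measure_cobb(curve, convention="eq5_printed")
            assert res_m.angle_deg + res_e.angle_deg == pytest.approx(180.0, abs=1e-9)

    def test_similarity_invariance(self):
        base = arc_curve(33, n=801)
        a0 = measure_cobb(base).angle_deg
        # translation and uniform scaling
        assert measure_cobb(base * 2.5 + np.array([17.0, -4.0])).angle_deg == pytest.approx(a0, abs=1e-9)
        # modest rotation (keeps rows monotone)
        assert measure_cobb(arc_curve(33, n=801, rot_deg=20)).angle_deg == pytest.approx(a0, abs=1e-7)

    def test_mirror_invariance(self):
        base = arc_curve(33, n=801)
        mirrored = base.copy()
        chord_col = base[0, 1]
        mirrored[:, 1] = 2 * chord_col - mirrored[:, 1]
        assert measure_cobb(mirrored).angle_deg == pytest.approx(
            measure_cobb(base).angle_deg, abs=1e-9
        )

    def test_angle_monotone_in_apex_deviation(self):
        r = np.linspace(0, 100, 201)
        prev = 0.0
        for d in (2, 5, 10, 20, 40):
            col = -d * np.sin(np.pi * r / 100)
            a = measure_cobb(np.column_stack([r, col])).angle_deg
            assert a > prev
            prev = a


class TestClassification:
    def test_straight_curve_is_not_scoliosis(self):
        curve = np.column_stack([np.arange(100.0), np.full(100, 30.0)])
        res = classify_scoliosis(curve, min_dev_px=3.0)
        assert not res.is_scoliosis and res.angle_deg == 0.0
        assert res.construction is None

    def test_deviation_threshold(self):
        r = np.linspace(0, 100, 101)
        small = np.column_stack([r, 2 * np.sin(np.pi * r / 100)])
        big = np.column_stack([r, 20 * np.sin(np.pi * r / 100)])
        assert not classify_scoliosis(small, min_dev_px=3.0).is_scoliosis
        res = classify_scoliosis(big, min_dev_px=3.0)
        assert res.is_scoliosis and res.angle_deg > 0
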