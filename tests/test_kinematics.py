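"""Forward kinematics, setup constants, closed-form solutions and sweeps."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from conftest import random_alignment_offsets
from microtarget.annotation import TargetOffsets
from microtarget.geometry import rotation_matrix
from microtarget.kinematics import (
    AxisLimits,
    DegenerateConfigurationError,
    InitialAlignment,
    KinConstants,
    MicrotomeState,
    compute_constants,
    forward_orientation,
    knife_angle_geometric,
    solve_knife_tilt,
    solve_sample_tilt,
    sweep_solutions,
    verticality_residual,
)

YHAT = np.array([0.0, 1.0, 0.0])
ZHAT = np.array([0.0, 0.0, 1.0])

# Setup constants for alignment (10, 10) deg, offsets (-3.3, 5.4) deg,
# frozen from an independent evaluation of the defining trigonometric
# products.
EXAMPLE_CONSTANTS = {
    "A": 0.9931706495384861,
    "B": 0.010979686282046059,
    "C": 0.020259660884356726,
    "D": 0.11489824644507235,
    "E": 0.11615294823830158,
    "F": 0.17287752090783384,
    "G": 0.09267859657897494,
    "H": 0.01634173711106852,
    "I": 0.9804371413451786,
}


class TestConstants:
    def test_zero_angles(self):
        k = compute_constants(InitialAlignment(0, 0), TargetOffsets(0, 0))
        assert k.A == 1 and k.I == 1
        for name in "BCDEFGH":
            assert getattr(k, name) == 0

    def test_example_setup_matches_independent_evaluation(self, example_setup):
        k = compute_constants(*example_setup)
        for name, expected in EXAMPLE_CONSTANTS.items():
            assert getattr(k, name) == pytest.approx(expected, abs=1e-14), name

    def test_all_constants_bounded_by_one(self, rng):
        for align, off in random_alignment_offsets(rng, 50, tilt_range=180, knife_range=180, offset_range=90):
            k = compute_constants(align, off)
            for name in "ABCDEFGHI":
                assert -1 <= getattr(k, name) <= 1

    def test_derived_ratio_consistency(self, example_setup):
        k = compute_constants(*example_setup)
        assert k.C1 == pytest.approx((-k.A * k.F + k.G) / (-k.A * k.I - k.H))
        assert k.C2 == pytest.approx(k.E / (-k.A * k.I - k.H))
        assert k.C3 == pytest.approx(k.A * k.I + k.H)


class TestForwardOrientation:
    def test_all_zero_angles_identity(self):
        F = forward_orientation(MicrotomeState(0, 0, 0), InitialAlignment(0, 0), TargetOffsets(0, 0))
        assert np.allclose(F.matrix, np.eye(3), atol=1e-12)

    def test_initial_tilt_cancellation(self):
        # theta_T = theta_IT, theta_R = 0: the leading Rx terms cancel,
        # leaving Rz(theta_IK + theta_to) Rx(theta_tr)
        align, off = InitialAlignment(7.0, 11.0), TargetOffsets(4.0, -9.0)
        F = forward_orientation(MicrotomeState(7.0, 0.0, 0.0), align, off)
        expected = rotation_matrix("z", align.theta_IK + off.theta_to) @ rotation_matrix("x", off.theta_tr)
        assert np.allclose(F.matrix, expected.matrix, atol=1e-12)

    def test_knife_angle_absent_from_forward_product(self, example_setup):
        a = forward_orientation(MicrotomeState(5, 40, 0), *example_setup)
        b = forward_orientation(MicrotomeState(5, 40, 30), *example_setup)
        assert np.allclose(a.matrix, b.matrix)


class TestSampleTiltSolution:
    def test_zero_offset_configuration_always_zero(self):
        k = compute_constants(InitialAlignment(0, 0), TargetOffsets(0, 0))
        for tR in np.linspace(-180, 180, 37):
            assert solve_sample_tilt(tR, k) == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize("t", [5.0, 20.0, -35.0])
    def test_pure_target_rotation_closed_form(self, t):
        # theta_IT = theta_IK = theta_to = 0, theta_tr = t:
        # theta_T(theta_R) = -arctan(tan(t) cos(theta_R))
        k = compute_constants(InitialAlignment(0, 0), TargetOffsets(0, t))
        for tR in np.linspace(-180, 180, 19):
            expected = -math.degrees(math.atan(math.tan(math.radians(t)) * math.cos(math.radians(tR))))
            assert solve_sample_tilt(tR, k) == pytest.approx(expected, abs=1e-10)
        assert solve_sample_tilt(0.0, k) == pytest.approx(-t, abs=1e-10)

    def test_verticality_of_solution(self, rng):
        # the solved tilt makes the transformed target normal horizontal
        for align, off in random_alignment_offsets(rng, 100):
            k = compute_constants(align, off)
            if k.degenerate:
                continue
            for tR in rng.uniform(-180, 180, 3):
                tT = solve_sample_tilt(tR, k)
                res = verticality_residual(MicrotomeState(tT, tR, 0), align, off)
                assert res < 1e-9

    def test_matches_bracketing_root_finder_oracle(self, rng):
        # independent oracle: solve (F yhat).zhat = 0 for theta_T by
        # bracketing root finding on the rotation-matrix product
        for align, off in random_alignment_offsets(rng, 60):
            k = compute_constants(align, off)
            if abs(k.C3) < 1e-3:
                continue

            for tR in rng.uniform(-180, 180, 2):
                def g(tT):
                    F = forward_orientation(MicrotomeState(tT, tR, 0), align, off)
                    return float(np.dot(F @ YHAT, ZHAT))

                root = brentq(g, -89.999999, 89.999999, xtol=1e-12)
                assert solve_sample_tilt(tR, k) == pytest.approx(root, abs=1e-8)

    def test_principal_value_range(self, rng):
        for align, off in random_alignment_offsets(rng, 50):
            k = compute_constants(align, off)
            if k.degenerate:
                continue
            for tR in rng.uniform(-180, 180, 4):
                assert -90 < solve_sample_tilt(tR, k) < 90

    def test_degenerate_configuration_signals(self):
        # target rotation 90 deg with zero initial tilt: C3 = A*I + H = 0
        k = compute_constants(InitialAlignment(0, 0), TargetOffsets(0, 90))
        assert k.degenerate
        with pytest.raises(DegenerateConfigurationError):
            solve_sample_tilt(0.0, k)


class TestKnifeTiltSolution:
    def test_zero_offset_configuration_always_zero(self):
        k = compute_constants(InitialAlignment(0, 0), TargetOffsets(0, 0))
        for tR in np.linspace(-180, 180, 37):
            assert solve_knife_tilt(tR, k) == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize("o", [10.0, 45.0, -60.0, 89.0])
    def test_pure_target_offset_at_zero_rotation(self, o):
        # theta_IT = theta_IK = theta_tr = 0, theta_to = o: theta_K(0) = o
        k = compute_constants(InitialAlignment(0, 0), TargetOffsets(o, 0))
        assert solve_knife_tilt(0.0, k) == pytest.approx(o, abs=1e-10)

    def test_matches_geometric_oracle(self, rng):
        # the closed form equals the signed horizontal-plane angle from
        # World y to F yhat, computed from the rotation-matrix product
        count = 0
        for align, off in random_alignment_offsets(rng, 400):
            k = compute_constants(align, off)
            if k.degenerate:
                continue
            for tR in rng.uniform(-180, 180, 3):
                closed = solve_knife_tilt(tR, k)
                oracle = knife_angle_geometric(tR, align, off, k)
                assert closed == pytest.approx(oracle, abs=1e-8)
                count += 1
        assert count >= 1000


class TestSweep:
    def test_zero_offset_sweep_all_zero_and_feasible(self):
        ss = sweep_solutions(InitialAlignment(0, 0), TargetOffsets(0, 0), step=1.0)
        assert np.allclose(ss.theta_T, 0) and np.allclose(ss.theta_K, 0)
        assert ss.feasible_mask.all()

    def test_extreme_offset_infeasible_subset(self):
        # a -60 deg target offset pushes some tilts beyond the 20 deg limit
        # (generous knife limit so only the sample-tilt constraint acts)
        ss = sweep_solutions(
            InitialAlignment(10, 10),
            TargetOffsets(-60, 5.4),
            AxisLimits(sample_tilt_max=20, knife_tilt_max=89),
        )
        feas = ss.feasible_mask
        assert 0 < feas.sum() < len(ss.entries)
        assert np.max(np.abs(ss.theta_T)) > 20.0

    def test_antisymmetry_under_half_turn(self, example_setup):
        k = compute_constants(*example_setup)
        for tR in np.linspace(-180, 179, 23):
            assert solve_sample_tilt(tR + 180, k) == pytest.approx(-solve_sample_tilt(tR, k), abs=1e-9)
            assert solve_knife_tilt(tR + 180, k) == pytest.approx(-solve_knife_tilt(tR, k), abs=1e-9)

    def test_period_360(self, example_setup):
        k = compute_constants(*example_setup)
        for tR in (-170.0, -45.0, 0.0, 80.0):
            assert solve_sample_tilt(tR + 360, k) == pytest.approx(solve_sample_tilt(tR, k), abs=1e-9)
            assert solve_knife_tilt(tR + 360, k) == pytest.approx(solve_knife_tilt(tR, k), abs=1e-9)

    def test_entries_sorted_and_residuals_tiny(self, example_setup):
        ss = sweep_solutions(*example_setup, step=0.5)
        assert np.all(np.diff(ss.theta_R) > 0)
        assert max(e.residual for e in ss.entries) < 1e-9

    def test_recorded_residual_matches_matrix_product(self, example_setup):
        align, off = example_setup
        ss = sweep_solutions(align, off, step=7.3)
        for e in ss.entries:
            direct = verticality_residual(MicrotomeState(e.theta_T, e.theta_R, e.theta_K), align, off)
            assert e.residual == pytest.approx(direct, abs=1e-12)

    def test_knife_consistency(self, example_setup):
        # rotating the solution's F by Rz(-theta_K) brings F yhat parallel
        # to World +/-y
        align, off = example_setup
        ss = sweep_solutions(align, off, step=11.0)
        for e in ss.entries:
            F = forward_orientation(MicrotomeState(e.theta_T, e.theta_R, e.theta_K), align, off)
            v = rotation_matrix("z", -e.theta_K) @ (F @ YHAT)
            assert abs(abs(v[1]) - 1.0) < 1e-9
            assert abs(v[0]) < 1e-9 and abs(v[2]) < 1e-9

    def test_best_feasible_minimises_pose(self, example_setup):
        ss = sweep_solutions(*example_setup)
        best = ss.best_feasible()
        score = abs(best.theta_T) + abs(best.theta_K)
        assert all(score <= abs(e.theta_T) + abs(e.theta_K) + 1e-12 for e in ss.feasible_entries())

    def test_invalid_step_rejected(self, example_setup):
        with pytest.raises(ValueError):
            sweep_solutions(*example_setup, step=0.0)


class TestLimits:
    def test_defaults(self):
        lim = AxisLimits()
        assert lim.sample_tilt_max == 20.0
        assert lim.feed_length_um == 200.0

    def test_positive_required(self):
        with pytest.raises(ValueError):
            AxisLimits(sample_tilt_max=-1)
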