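from fractions import Fraction

import numpy as np
import pytest

import tendrilkin as tk
from tendrilkin.errors import ContractError, UnsupportedConditionError
from tendrilkin.kinematics import acceleration, jerk, velocity

from conftest import make_trajectory


def _poly_series(coeffs, t):
    return sum(c * t**i for i, c in enumerate(coeffs))


def _rational_divided_differences(s, t, order):
    """Independent oracle: repeated divided differences in exact rational
    arithmetic (no floating-point error)."""
    # floats are dyadic rationals, so Fraction(x) is an exact lift
    s = [Fraction(float(x)) for x in s]
    t = [Fraction(float(x)) for x in t]
    for _ in range(order):
        s = [(s[i] - s[i - 1]) / (t[i] - t[i - 1]) for i in range(1, len(s))]
        t = t[1:]
    return np.array([float(x) for x in s])


class TestDistanceSeries:
    def test_vertical_coordinate_ignored(self):
        support = tk.SupportSpec(kind="artificial", axis_x=0.0, axis_z=0.0,
                                 radius=1e-12, height=600.0)
        xyz = np.array([[10.0, 999.0, 0.0]] * 4)
        traj = tk.Trajectory("p", "AC", [0, 1, 2, 3], xyz, grasped=True)
        np.testing.assert_allclose(tk.distance_series(traj, support), 10.0, atol=1e-9)

    def test_three_four_five_triangle(self):
        support = tk.SupportSpec(kind="artificial", radius=1e-12, height=1.0)
        xyz = np.array([[3.0, 7.0, 4.0]] * 4)
        traj = tk.Trajectory("p", "AC", [0, 1, 2, 3], xyz, grasped=True)
        np.testing.assert_allclose(tk.distance_series(traj, support), 5.0, atol=1e-9)

    def test_floored_at_zero_inside_support(self):
        support = tk.SupportSpec(kind="artificial", radius=6.0, height=1.0)
        traj = tk.Trajectory("p", "AC", [0, 1, 2, 3], np.zeros((4, 3)), grasped=True)
        np.testing.assert_array_equal(tk.distance_series(traj, support), 0.0)

    def test_no_support_condition_rejected(self):
        traj = tk.Trajectory("p", "CC", [0, 1, 2, 3], np.zeros((4, 3)))
        with pytest.raises(UnsupportedConditionError):
            tk.distance_series(traj, tk.SupportSpec(kind="none"))

    def test_moving_support_uses_motion_trace(self):
        """A tip riding a swaying axis at fixed offset has constant distance."""
        t = np.arange(6.0)
        trace = np.column_stack([3 * np.sin(t), 2 * np.cos(t)])
        support = tk.SupportSpec(kind="biological", axis_x=50.0, axis_z=0.0,
                                 radius=2.0, height=400.0, motion_trace=trace)
        axis = support.axis_positions(6)
        xyz = np.column_stack([axis[:, 0] + 10.0, np.zeros(6), axis[:, 1]])
        traj = tk.Trajectory("p", "BC", t, xyz, grasped=True)
        np.testing.assert_allclose(tk.distance_series(traj, support), 8.0, atol=1e-9)

    def test_vertical_motion_invariance(self):
        support = tk.SupportSpec(kind="artificial", axis_x=40.0, radius=3.0, height=1.0)
        rng = np.random.default_rng(5)
        xyz = rng.normal(0, 20, (8, 3))
        t = np.arange(8.0)
        s1 = tk.distance_series(tk.Trajectory("p", "AC", t, xyz, grasped=True), support)
        xyz2 = xyz.copy()
        xyz2[:, 1] = rng.normal(0, 500, 8)
        s2 = tk.distance_series(tk.Trajectory("p", "AC", t, xyz2, grasped=True), support)
        np.testing.assert_array_equal(s1, s2)


class TestFiniteDifferences:
    @pytest.mark.parametrize(
        "s,t,expected",
        [([10, 8], [0, 1], [-2.0]),
         ([5, 5, 5, 5], [0, 1, 2, 3], [0, 0, 0]),
         ([0, 1, 4, 9], [0, 1, 2, 3], [1, 3, 5])],
    )
    def test_velocity_examples(self, s, t, expected):
        np.testing.assert_allclose(velocity(s, t), expected)

    def test_acceleration_and_jerk_examples(self):
        np.testing.assert_allclose(acceleration([1, 3, 5], [1, 2, 3]), [2, 2])
        np.testing.assert_allclose(jerk([2, 2], [2, 3]), [0.0])
        np.testing.assert_allclose(jerk([0, 6], [0, 2]), [3.0])
        assert len(acceleration([4.0], [1.0])) == 0  # boundary: no differences

    def test_contract_errors(self):
        with pytest.raises(ContractError):
            velocity([1, 2, 3], [0, 1])
        with pytest.raises(ContractError):
            velocity([1, 2], [1, 1])

    @pytest.mark.parametrize("degree", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rational_oracle_on_random_polynomials(self, degree, seed):
        """v/a/j agree with exact rational divided differences to 1e-12 relative."""
        rng = np.random.default_rng(100 * degree + seed)
        coeffs = rng.integers(-9, 10, degree + 1).astype(float)
        t = np.round(np.cumsum(rng.uniform(0.25, 2.0, 16)), 6)
        s = _poly_series(coeffs, t)
        v = velocity(s, t)
        a = acceleration(v, t[1:])
        j = jerk(a, t[2:])
        for arr, order in ((v, 1), (a, 2), (j, 3)):
            oracle = _rational_divided_differences(s, t, order)
            np.testing.assert_allclose(arr, oracle, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("degree", [0, 1, 2, 3])
    def test_polynomial_annihilation(self, degree):
        """The (k+1)-th divided difference of a degree-k polynomial vanishes."""
        t = np.arange(12.0)
        coeffs = np.arange(1, degree + 2, dtype=float)
        arr = _poly_series(coeffs, t)
        tt = t
        for _ in range(degree + 1):
            arr = velocity(arr, tt)
            tt = tt[1:]
        np.testing.assert_allclose(arr, 0.0, atol=1e-9)

    def test_time_scale_covariance(self):
        """Scaling t by c scales v by 1/c, a by 1/c^2, j by 1/c^3."""
        rng = np.random.default_rng(7)
        t = np.cumsum(rng.uniform(0.1, 1.0, 20))
        s = rng.normal(0, 10, 20)
        c = 3.7
        v1, v2 = velocity(s, t), velocity(s, c * t)
        a1, a2 = acceleration(v1, t[1:]), acceleration(v2, c * t[1:])
        j1, j2 = jerk(a1, t[2:]), jerk(a2, c * t[2:])
        np.testing.assert_allclose(v2 * c, v1, rtol=1e-12)
        np.testing.assert_allclose(a2 * c**2, a1, rtol=1e-12)
        np.testing.assert_allclose(j2 * c**3, j1, rtol=1e-12)


class TestMovementMeasures:
    def test_duration_to_final_grasp(self, trajectory_factory):
        traj, _ = trajectory_factory(np.linspace(0, 111, 40), np.linspace(50, 0, 40))
        assert tk.movement_duration(traj) == pytest.approx(111.0)

    def test_duration_stops_at_mid_series_grasp(self, pole):
        t = np.arange(10.0)
        traj = make_trajectory(t, np.linspace(20, 2, 10), pole)
        traj.grasp_index = 6
        assert tk.movement_duration(traj) == pytest.approx(6.0)

    def test_drop_index_override_for_ungrasped(self):
        traj = tk.Trajectory("p", "CC", np.arange(8.0), np.random.default_rng(0).normal(0, 1, (8, 3)))
        assert tk.movement_duration(traj) == pytest.approx(7.0)
        assert tk.movement_duration(traj, drop_index=4) == pytest.approx(4.0)

    def test_mean_velocity_modes(self, trajectory_factory):
        traj, pole = trajectory_factory(np.arange(5.0), [10, 8, 10, 8, 10])
        profile = tk.compute_profile(traj, pole)
        assert tk.mean_velocity(profile, "absolute") == pytest.approx(2.0)
        assert tk.mean_velocity(profile, "signed") == pytest.approx(0.0)

    def test_constant_speed_approach(self, trajectory_factory):
        rate = 1.582
        t = np.linspace(0, 50, 80)
        traj, pole = trajectory_factory(t, 100 - rate * t)
        profile = tk.compute_profile(traj, pole)
        assert tk.mean_velocity(profile) == pytest.approx(rate, rel=1e-9)

    def test_profile_length_relations(self, simple_trajectory, pole):
        p = tk.compute_profile(simple_trajectory, pole)
        n = len(p.t)
        assert (len(p.s), len(p.v), len(p.a), len(p.j)) == (n, n - 1, n - 2, n - 3)

    def test_smoothing_window_must_be_odd(self, simple_trajectory, pole):
        with pytest.raises(ContractError):
            tk.compute_profile(simple_trajectory, pole, smooth_window=4)
        p = tk.compute_profile(simple_trajectory, pole, smooth_window=3)
        assert len(p.s) == len(p.t)
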