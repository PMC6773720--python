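"""Trajectory kinematics against independent numerical oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from gravipursuit import trajectory as traj

from conftest import DESIGN_CELLS


def ode_oracle(params, t_eval):
    """Fourth/fifth-order adaptive integration of the drag equations."""

    def rhs(_t, state):
        x, y, vx, vy = state
        k = params.c / params.m
        g_signed = -params.sign * params.g
        return [vx, vy, -k * vx, g_signed - k * vy]

    v0y = params.sign * params.v_yi
    sol = solve_ivp(rhs, (0.0, float(np.max(t_eval))),
                    [params.start_x, params.start_y, params.v_xi, v0y],
                    t_eval=np.atleast_1d(t_eval), rtol=1e-11, atol=1e-13)
    return sol


class TestPosition:
    def test_initial_condition(self):
        p = traj.make_params(1.0, 3.0, 6.0)
        st = traj.position(p, 0.0)
        assert st.x == pytest.approx(p.start_x)
        assert st.y == pytest.approx(p.start_y)
        assert (st.vx, st.vy) == (pytest.approx(3.0), pytest.approx(6.0))

    def test_ballistic_limit_closed_form(self):
        p = traj.make_params(1.0, 3.0, 6.0, c=1e-12)
        st = traj.position(p, 0.5)
        assert st.y - p.start_y == pytest.approx(6 * 0.5 - 4.905 * 0.25,
                                                 abs=1e-9)

    @pytest.mark.parametrize("gravity,vy,vx", DESIGN_CELLS)
    def test_matches_ode_oracle_everywhere(self, gravity, vy, vx):
        p = traj.params_for(gravity, vx, vy)
        T = traj.return_time(p)
        ts = np.linspace(1e-3, T, 25)
        sol = ode_oracle(p, ts)
        st = traj.position(p, ts)
        assert np.max(np.abs(st.x - sol.y[0])) < 1e-6
        assert np.max(np.abs(st.y - sol.y[1])) < 1e-6

    def test_negative_time_rejected(self):
        p = traj.make_params(1.0, 3.0, 6.0)
        with pytest.raises(traj.TrajectoryError):
            traj.position(p, -0.1)

    def test_velocities_are_analytic_derivatives(self):
        p = traj.make_params(1.3, 4.0, 4.5)
        t, h = 0.4, 1e-6
        a = traj.position(p, t - h)
        b = traj.position(p, t + h)
        st = traj.position(p, t)
        assert st.vx == pytest.approx((b.x - a.x) / (2 * h), rel=1e-6)
        assert st.vy == pytest.approx((b.y - a.y) / (2 * h), rel=1e-6)


class TestReturnTime:
    def test_ballistic_two_v_over_g(self):
        p = traj.make_params(1.0, 3.0, 6.0, c=1e-12)
        assert traj.return_time(p) == pytest.approx(2 * 6.0 / 9.81, abs=1e-6)

    def test_mirror_symmetry_of_flight_time(self):
        up = traj.make_params(1.0, 3.0, 6.0, c=1e-12)
        down = traj.make_params(-1.0, 3.0, 6.0, c=1e-12)
        assert traj.return_time(down) == pytest.approx(traj.return_time(up),
                                                       abs=1e-12)

    def test_drag_flight_time_matches_ode(self):
        p = traj.make_params(1.0, 3.0, 6.0)
        T = traj.return_time(p)
        sol = ode_oracle(p, [T])
        assert abs(sol.y[1][-1] - p.start_y) < 1e-6


class TestCoincidenceX:
    def test_ballistic_symmetry(self):
        p = traj.make_params(1.0, 3.0, 6.0, c=1e-12)
        assert traj.coincidence_x(p) == pytest.approx(-p.start_x, abs=1e-6)

    def test_drag_matches_ode(self):
        p = traj.make_params(1.0, 3.0, 4.5)
        T = traj.return_time(p)
        sol = ode_oracle(p, [T])
        assert abs(traj.coincidence_x(p) - sol.y[0][-1]) < 1e-6

    def test_ballistic_scaling_law(self):
        # T = 2 v_yi / g: scaling (g, v_yi, v_xi) by (k^2, k, k) preserves
        # the span; scaling only (g, v_yi) by (k^2, k) halves it for k=2
        base = traj.make_params(1.0, 3.0, 4.5, c=0.0)
        same = traj.make_params(4.0, 6.0, 9.0, c=0.0)
        halved = traj.make_params(4.0, 3.0, 9.0, c=0.0)
        span = lambda p: traj.coincidence_x(p) - p.start_x
        assert span(same) == pytest.approx(span(base), rel=1e-9)
        assert span(halved) == pytest.approx(span(base) / 2, rel=1e-9)


class TestOcclusionOnset:
    def test_last_half_hidden(self):
        p = traj.make_params(1.0, 3.0, 6.0, c=1e-12)
        assert traj.occlusion_onset(p, 0.5) == pytest.approx(0.61162, abs=1e-5)

    def test_short_occlusion_hides_last_quarter(self):
        p = traj.make_params(1.0, 3.0, 6.0, c=1e-12)
        T = traj.return_time(p)
        assert traj.occlusion_onset(p, 0.25) == pytest.approx(0.75 * T)

    @pytest.mark.parametrize("bad", [0.1, 0.3, 0.44, 0.51, 0.6])
    def test_fraction_outside_intervals_rejected(self, bad):
        p = traj.make_params(1.0, 3.0, 6.0)
        with pytest.raises(traj.TrajectoryError):
            traj.occlusion_onset(p, bad)

    def test_consistency_with_return_time(self):
        p = traj.make_params(0.85, 4.0, 4.5)
        assert traj.occlusion_onset(p, 0.45) == pytest.approx(
            0.55 * traj.return_time(p), rel=1e-12)


class TestPredictTtc1g:
    def test_free_fall_from_rest(self):
        assert traj.predict_ttc_1g(traj.TtcQuery(0.0, 4.905)) == pytest.approx(1.0)

    def test_factorable_quadratic(self):
        # 4.905 t^2 + 9.81 t - 14.715 = 0  ->  t = 1
        q = traj.TtcQuery(v_y_last=-9.81, d_y=14.715)
        assert traj.predict_ttc_1g(q) == pytest.approx(1.0, abs=1e-12)

    def test_upward_start_matches_bisection(self):
        q = traj.TtcQuery(v_y_last=0.2, d_y=1.76)
        root = bisect(lambda t: 4.905 * t**2 - 0.2 * t - 1.76, 1e-9, 10,
                      xtol=1e-12)
        assert traj.predict_ttc_1g(q) == pytest.approx(root, abs=1e-9)

    def test_at_coincidence_moving_toward(self):
        assert traj.predict_ttc_1g(traj.TtcQuery(-1.0, 0.0)) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(traj.TrajectoryError):
            traj.TtcQuery(0.0, -0.1)

    def test_grid_against_bisection_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            v = float(rng.uniform(-8, 8))
            d = float(rng.uniform(0.01, 5))
            q = traj.TtcQuery(v_y_last=v, d_y=d)
            root = bisect(lambda t: 4.905 * t**2 - v * t - d, 1e-12, 20,
                          xtol=1e-12)
            assert traj.predict_ttc_1g(q) == pytest.approx(root, abs=1e-9)


class TestInvariants:
    def test_drag_to_zero_convergence(self):
        for g, vy, vx in DESIGN_CELLS:
            pb = traj.make_params(g, vx, vy, c=0.0)
            pe = traj.make_params(g, vx, vy, c=1e-10)
            ts = np.linspace(0, traj.return_time(pb), 50)
            sb, se = traj.position(pb, ts), traj.position(pe, ts)
            assert np.max(np.hypot(sb.x - se.x, sb.y - se.y)) < 1e-6

    def test_mirror_symmetry_about_midheight(self):
        up = traj.make_params(1.0, 3.0, 6.0)
        down = traj.make_params(-1.0, 3.0, 6.0)
        ts = np.linspace(0, traj.return_time(up), 40)
        yu = traj.position(up, ts).y
        yd = traj.position(down, ts).y
        # start heights 0.5 and 3.5 -> reflection about y = 2.0
        assert np.max(np.abs((4.0 - yu) - yd)) < 1e-12

    def test_apex_at_x_zero_in_ballistic_limit(self):
        for g, vy, vx in DESIGN_CELLS:
            p = traj.make_params(g, vx, vy, c=0.0)
            assert abs(traj.position(p, traj._peak_time(p)).x) < 1e-9

    def test_apex_offset_small_with_drag(self):
        # drag skews the parabola slightly; the extremum stays near x=0
        worst = max(abs(traj.position(p, traj._peak_time(p)).x)
                    for g, vy, vx in DESIGN_CELLS
                    for p in [traj.params_for(g, vx, vy)])
        assert worst < 0.1

    def test_query_mirrors_inverted_geometry(self):
        up = traj.params_for(1.0, 3.0, 6.0)
        down = traj.params_for(-1.0, 3.0, 6.0)
        t_occ = traj.occlusion_onset(up, 0.475)
        qu = traj.ttc_query_at(up, t_occ)
        qd = traj.ttc_query_at(down, t_occ)
        assert qu.v_y_last == pytest.approx(qd.v_y_last, abs=1e-12)
        assert qu.d_y == pytest.approx(qd.d_y, abs=1e-12)


def test_sample_trajectory_schema():
    p = traj.params_for(1.0, 3.0, 6.0)
    t_occ = traj.occlusion_onset(p, 0.25)
    data = traj.sample_trajectory(p, rate_hz=85.0, t_occ=t_occ)
    assert set(data) == {"t", "x", "y", "vx", "vy", "visible"}
    assert np.all(np.diff(data["t"]) > 0)
    assert data["visible"][0] == 1 and data["visible"][-1] == 0
    assert np.all(data["t"][data["visible"] == 0] >= t_occ)
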