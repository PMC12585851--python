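import numpy as np
import pytest

from stridecost.pendulum import (
    DEFAULT_NOISE_GRID,
    WalkerParams,
    apply_step_transition,
    control_law,
    deadbeat_gains,
    find_nominal_gait,
    integrate_stance,
    noise_sweep,
    simulate_walk,
    _next_midstance_speed,
    _time_of_flight,
)


@pytest.fixture(scope="module")
def nominal():
    return find_nominal_gait(0.4, WalkerParams())


class TestStanceDynamics:
    def test_energy_is_conserved_along_stance(self):
        traj = integrate_stance(-0.3, 0.6, 0.3)
        E = 0.5 * traj.theta_dot**2 + np.cos(traj.theta)
        assert np.max(np.abs(E - E[0])) < 1e-8

    def test_start_at_midstance_reports_initial_speed(self):
        traj = integrate_stance(0.0, 0.4, 0.3)
        assert traj.mid_stance_speed == pytest.approx(0.4, abs=1e-10)

    def test_midstance_speed_matches_energy_closed_form(self):
        theta0, w0 = -0.3, 0.8
        traj = integrate_stance(theta0, w0, 0.3)
        expected = np.sqrt(w0**2 + 2.0 * (np.cos(theta0) - 1.0))
        assert traj.mid_stance_speed == pytest.approx(expected, abs=1e-8)

    def test_insufficient_energy_flags_fall(self):
        traj = integrate_stance(-0.3, 0.05, 0.3)
        assert traj.fell

    def test_ode_duration_agrees_with_quadrature_stepper(self):
        theta0, w0, trig = -0.25, 0.7, 0.25
        traj = integrate_stance(theta0, w0, trig)
        E = 0.5 * w0**2 + np.cos(theta0)
        assert traj.duration == pytest.approx(_time_of_flight(E, theta0, trig), abs=1e-7)


class TestStepTransition:
    def test_collinear_legs_no_pushoff_is_lossless(self):
        v_plus, work, loss = apply_step_transition(0.5, 0.0, 0.0)
        assert v_plus == pytest.approx(0.5) and work == 0.0 and loss == 0.0

    def test_passive_transition_projects_velocity(self):
        v, two_alpha = 0.62, 0.58
        v_plus, work, loss = apply_step_transition(v, two_alpha, 0.0)
        assert v_plus == pytest.approx(v * np.cos(two_alpha), abs=1e-10)
        assert loss == pytest.approx(0.5 * v**2 * np.sin(two_alpha) ** 2, abs=1e-10)
        assert work == 0.0

    def test_steady_pushoff_is_energy_neutral(self):
        v, alpha = 0.62, 0.29
        P = v * np.tan(alpha)
        v_plus, work, loss = apply_step_transition(v, 2 * alpha, P)
        assert v_plus == pytest.approx(v, abs=1e-10)
        assert work == pytest.approx(loss, abs=1e-10)

    def test_kinetic_energy_bookkeeping(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            v = rng.uniform(0.1, 1.0)
            two_alpha = rng.uniform(0.0, 1.2)
            P = rng.uniform(0.0, 0.5)
            v_plus, work, loss = apply_step_transition(v, two_alpha, P)
            assert 0.5 * v_plus**2 == pytest.approx(0.5 * v**2 + work - loss, abs=1e-10)


class TestControlAndNominalGait:
    def test_nominal_gait_is_fixed_point_over_50_steps(self, nominal):
        params = WalkerParams(n_steps=50, seed=0, nominal=nominal)
        res = simulate_walk(params)
        costs = [s.step_cost for s in res.steps]
        assert np.std(costs) <= 1e-8
        assert res.normalized_mean == pytest.approx(1.0, abs=1e-8)

    def test_nominal_speed_constraint_met(self, nominal):
        assert nominal.step_length / nominal.step_time == pytest.approx(0.4, abs=1e-6)

    def test_perturbing_step_length_never_lowers_cost(self, nominal):
        from stridecost.pendulum import _periodic_gait

        params = WalkerParams()
        for fac in (0.9, 1.1):
            alpha = np.arcsin(fac * nominal.step_length / 2.0)
            alt = _periodic_gait(alpha, 0.4, params)
            assert alt.cost_rate >= nominal.cost_rate - 1e-12

    def test_optimizer_restarts_agree(self):
        a = find_nominal_gait(0.4, WalkerParams())
        b = find_nominal_gait(0.4, WalkerParams(alpha_bounds=(0.05, 1.0)))
        assert a.cost_rate == pytest.approx(b.cost_rate, abs=1e-6)

    def test_no_deviation_no_noise_returns_nominal_commands(self, nominal):
        params = WalkerParams(nominal=nominal)
        P, s = control_law(nominal.mid_stance_speed, params, rng=None)
        assert P == pytest.approx(nominal.pushoff, abs=1e-12)
        assert s == pytest.approx(nominal.step_length, abs=1e-12)

    def test_zero_gains_give_open_loop_commands(self, nominal):
        params = WalkerParams(nominal=nominal, gain_pushoff=0.0, gain_step=0.0)
        P, s = control_law(nominal.mid_stance_speed + 0.1, params, rng=None)
        assert (P, s) == (pytest.approx(nominal.pushoff), pytest.approx(nominal.step_length))

    def test_default_gains_deadbeat_the_linearized_stride_map(self, nominal):
        k_P, k_s = deadbeat_gains(nominal)
        v, P, s = nominal.mid_stance_speed, nominal.pushoff, nominal.step_length
        h = 1e-6
        closed = lambda vv: _next_midstance_speed(
            vv, P + k_P * (vv - v), s + k_s * (vv - v)
        )
        jac = (closed(v + h) - closed(v - h)) / (2 * h)
        assert abs(jac) < 1e-3  # spectral radius << 1

    def test_injected_deviation_decays_geometrically(self, nominal):
        k_P, k_s = deadbeat_gains(nominal)
        v = nominal.mid_stance_speed * 1.05
        devs = []
        for _ in range(4):
            dv = v - nominal.mid_stance_speed
            v = _next_midstance_speed(
                v, nominal.pushoff + k_P * dv, nominal.step_length + k_s * dv
            )
            devs.append(abs(v - nominal.mid_stance_speed))
        assert devs[0] < 0.05 * nominal.mid_stance_speed * 0.2
        assert devs[-1] < 1e-10


class TestSimulateWalk:
    def test_same_seed_is_bit_identical(self):
        a = simulate_walk(WalkerParams(n_steps=200, seed=11, sigma_pushoff=0.02))
        b = simulate_walk(WalkerParams(n_steps=200, seed=11, sigma_pushoff=0.02))
        assert a.steps == b.steps
        assert a.mean_cost_rate == b.mean_cost_rate

    def test_zero_noise_steps_are_identical(self):
        res = simulate_walk(WalkerParams(n_steps=50, seed=0))
        first = res.steps[0]
        for st in res.steps[1:]:
            assert st.step_cost == pytest.approx(first.step_cost, abs=1e-8)
        assert res.sd_step_cost <= 1e-8 and res.n_falls == 0

    def test_small_motor_noise_raises_mean_cost(self):
        raised = 0
        for seed in range(10):
            res = simulate_walk(
                WalkerParams(n_steps=2000, seed=seed, sigma_pushoff=0.01, sigma_step=0.01)
            )
            raised += res.normalized_mean > 1.0
        assert raised == 10

    def test_costs_are_nonnegative(self):
        res = simulate_walk(WalkerParams(n_steps=500, seed=3, sigma_sense=0.05))
        for st in res.steps:
            assert st.pushoff_work >= 0 and st.heelstrike_loss >= 0 and st.step_cost >= 0


class TestNoiseSweep:
    def test_zero_noise_row_self_normalizes(self):
        df = noise_sweep(WalkerParams(n_steps=200, seed=1), [0.0, 0.02], "motor")
        row = df.loc[df.sigma == 0].iloc[0]
        assert row.normalized_mean == pytest.approx(1.0, abs=1e-12)
        assert row.normalized_sd == pytest.approx(0.0, abs=1e-8)

    def test_grid_without_zero_rejected(self):
        with pytest.raises(ValueError, match="sigma = 0"):
            noise_sweep(WalkerParams(), [0.01, 0.02], "motor")

    @pytest.mark.parametrize("mode", ["motor", "sensory"])
    def test_cost_and_sd_increase_with_noise(self, mode):
        df = noise_sweep(
            WalkerParams(n_steps=2000, seed=42), list(DEFAULT_NOISE_GRID), mode
        )
        assert np.all(np.diff(df.normalized_mean) > 0)
        assert np.all(np.diff(df.normalized_sd) > 0)
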