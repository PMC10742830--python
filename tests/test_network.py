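import numpy as np
import pytest

import criticality as ca
from criticality.network import (Network, NetworkSpec, RandomConnectivity,
                                 berry_coupling_input, build_network,
                                 wu_diffusion)


class TestCouplingArithmetic:
    def test_external_only(self):
        W = np.zeros((3, 3))
        assert berry_coupling_input([1, 2, 3], W, 0.25, 0) == 0.25

    def test_single_incoming_connection(self):
        # two units, source 1 -> target 0 at the published mutual weight
        W = np.zeros((2, 2))
        W[1, 0] = 0.0005
        assert berry_coupling_input([0.0, 10.0], W, 0.0, 0) == \
            pytest.approx(0.005, abs=1e-15)

    def test_symmetric_uniform_coupling(self):
        w, m = 0.3, 1.7
        W = np.full((4, 4), w)
        got = berry_coupling_input([m] * 4, W, 0.1, 2)
        assert got == pytest.approx(3 * w * m + 0.1, rel=1e-14)

    def test_diagonal_excluded(self):
        W = np.eye(3)  # only self-connections: all ignored
        assert berry_coupling_input([5, 5, 5], W, 0.0, 1) == 0.0

    def test_wu_diffusion_zero_weights(self):
        D = wu_diffusion(np.ones((3, 4)), np.zeros(3))
        assert np.array_equal(D, np.zeros((3, 4)))

    def test_wu_diffusion_self_inclusion(self):
        state = np.array([[1.0, 2.0, 3.0, 4.0]])
        D = wu_diffusion(state, np.array([1.0]))
        assert np.array_equal(D, state)

    def test_wu_diffusion_shared_sum(self):
        S = np.zeros((3, 4))
        S[:, 0] = [1.0, 2.0, 3.0]
        D = wu_diffusion(S, np.ones(3))
        assert np.all(D[:, 0] == 6.0)
        assert np.all(D[:, 1:] == 0.0)


class TestBuildNetwork:
    def test_uniform_weights_zero_diagonal(self, spec4):
        net = build_network(spec4)
        assert net.weights.shape == (4, 4)
        assert np.all(np.diag(net.weights) == 0.0)
        off = net.weights[~np.eye(4, dtype=bool)]
        assert np.all(off == 0.0005)

    def test_same_seed_same_weights(self):
        rc = RandomConnectivity(mean=0.000035, sd=0.00001)
        a = build_network(NetworkSpec(n_oscillators=8, weights=rc, seed=42,
                                      input_map=(0,)))
        b = build_network(NetworkSpec(n_oscillators=8, weights=rc, seed=42,
                                      input_map=(0,)))
        assert np.array_equal(a.weights, b.weights)

    def test_random_weight_statistics(self):
        rc = RandomConnectivity(mean=0.000035, sd=0.00001)
        net = build_network(NetworkSpec(n_oscillators=64, weights=rc, seed=3,
                                        input_map=(0,)))
        off = net.weights[~np.eye(64, dtype=bool)]
        assert np.all(off >= 0.0)
        se = rc.sd / np.sqrt(off.size)
        assert abs(off.mean() - rc.mean) < 3 * se

    def test_input_map_validation(self):
        with pytest.raises(ValueError):
            NetworkSpec(n_oscillators=2, input_map=(0, 2))
        with pytest.raises(ValueError):
            NetworkSpec(n_oscillators=4, input_map=(1, 1))

    def test_wu_restrictions(self):
        with pytest.raises(ValueError):
            NetworkSpec(model="wu", normalisation="dynamic", input_map=(0,))
        with pytest.raises(ValueError):
            NetworkSpec(model="wu", learning=ca.HebbianSettings(), input_map=(0,))

    def test_explicit_matrix_shape_checked(self):
        with pytest.raises(ValueError):
            build_network(NetworkSpec(n_oscillators=3, weights=np.ones((2, 2)),
                                      input_map=(0,)))


def _reference_run(net, rows, schedule, stepper):
    """Clamp protocol re-implemented on the generic integrator and the pure
    Python vector field -- the independent route the kernels must match."""
    osc = np.asarray(net.spec.input_map)
    out = [net.state.ravel().copy()]
    y = net.state.ravel().copy()
    for row in np.atleast_2d(rows):
        eps = np.zeros(net.n_total)
        eps[osc] = row
        deriv = lambda t, yy: net.derivatives(t, yy, eps)
        for step in range(schedule.steps_per_sample):
            y = stepper(deriv, y, 0.0, schedule.step_size)
            if (step + 1) % schedule.record_stride == 0:
                out.append(y.copy())
    return np.vstack(out)


class TestClampedSimulation:
    @pytest.mark.parametrize("integrator", ["rk4", "fehlberg"])
    def test_kernel_matches_reference_integrator_berry(self, integrator):
        spec = NetworkSpec(model="berry", n_oscillators=3, weights=0.0005,
                           input_map=(0, 1, 2), integrator=integrator)
        sched = ca.ClampSchedule(steps_per_sample=200, step_size=0.1,
                                 record_stride=10)
        rows = np.array([[0.05, 0.02, 0.0], [0.01, 0.06, 0.03]])
        traj = build_network(spec).simulate_clamped(rows, sched)
        stepper = ca.rk4_step if integrator == "rk4" else ca.fehlberg_step
        ref = _reference_run(build_network(spec), rows, sched, stepper)
        assert np.allclose(traj.states, ref, rtol=0, atol=1e-12)

    def test_kernel_matches_reference_integrator_wu(self):
        spec = NetworkSpec(model="wu", n_oscillators=3, weights=0.0001,
                           input_map=(0, 1, 2))
        sched = ca.ClampSchedule(steps_per_sample=100, step_size=0.001,
                                 record_stride=10)
        rows = np.array([[0.01, 0.02, 0.005]])
        traj = build_network(spec).simulate_clamped(rows, sched)
        ref = _reference_run(build_network(spec), rows, sched, ca.rk4_step)
        assert np.allclose(traj.states, ref, rtol=0, atol=1e-9)

    def test_decoupled_unit_matches_free_run(self, short_schedule):
        """With zero weights a single clamped oscillator is exactly the free
        single-oscillator integration at constant drive."""
        spec = NetworkSpec(model="berry", n_oscillators=1, weights=0.0,
                           input_map=(0,))
        traj = build_network(spec).simulate_clamped([[0.05]], short_schedule)
        free = ca.integrate(
            lambda t, y: ca.berry_derivatives(y, ca.BerryParams(), 0.05),
            [1.0, 1.0, 1.0, 1.0], short_schedule.steps_per_sample,
            short_schedule)
        assert np.allclose(traj.states, free.states, rtol=0, atol=1e-12)

    def test_input_locality(self, short_schedule):
        """Zero coupling: an oscillator with no attribute stays exactly on
        its unperturbed orbit."""
        spec = NetworkSpec(model="berry", n_oscillators=2, weights=0.0,
                           input_map=(0,))
        traj = build_network(spec).simulate_clamped([[0.08]], short_schedule)
        free = ca.integrate(
            lambda t, y: ca.berry_derivatives(y, ca.BerryParams(), 0.0),
            [1.0, 1.0, 1.0, 1.0], short_schedule.steps_per_sample,
            short_schedule)
        for i, var in enumerate(("m", "f", "p", "g")):
            assert np.array_equal(traj.channel(f"osc1:{var}"),
                                  free.states[:, i])

    def test_runs_are_bit_identical(self, spec4, short_schedule):
        rows = np.array([[0.05, 0.02, 0.07, 0.01], [0.03, 0.03, 0.03, 0.03]])
        a = build_network(spec4).simulate_clamped(rows, short_schedule)
        b = build_network(spec4).simulate_clamped(rows, short_schedule)
        assert np.array_equal(a.states, b.states)
        assert a.sample_boundaries == b.sample_boundaries

    def test_state_carries_over_between_samples(self, spec4, short_schedule):
        """Presenting [r1, r2] in one call equals presenting r1 then r2 to
        the same network -- no reset or discontinuity at the boundary."""
        rows = np.array([[0.05, 0.02, 0.07, 0.01], [0.03, 0.03, 0.03, 0.03]])
        joint = build_network(spec4).simulate_clamped(rows, short_schedule)
        net = build_network(spec4)
        first = net.simulate_clamped(rows[:1], short_schedule)
        second = net.simulate_clamped(rows[1:], short_schedule)
        n_rec = short_schedule.records_per_sample
        assert np.array_equal(joint.states[:1 + n_rec], first.states)
        assert np.array_equal(joint.states[1 + n_rec:], second.states[1:])

    def test_reset_per_sample_gives_identical_windows(self, short_schedule):
        spec = NetworkSpec(model="berry", n_oscillators=4, weights=0.0005,
                           input_map=(0, 1, 2, 3), reset_per_sample=True)
        rows = np.tile([0.05, 0.02, 0.07, 0.01], (2, 1))
        traj = build_network(spec).simulate_clamped(rows, short_schedule)
        assert np.array_equal(traj.window(0), traj.window(1))

    def test_row_width_mismatch_rejected(self, spec4, short_schedule):
        with pytest.raises(ValueError):
            build_network(spec4).simulate_clamped([[0.1, 0.2]], short_schedule)

    def test_blowup_reports_sample_index(self, short_schedule):
        spec = NetworkSpec(model="berry", n_oscillators=2, weights=0.0005,
                           input_map=(0, 1))
        with pytest.raises(ca.NumericalBlowUp) as exc:
            build_network(spec).simulate_clamped(
                np.array([[0.01, 0.01], [1e9, 1e9]]),
                ca.ClampSchedule(steps_per_sample=50_000, step_size=0.1))
        assert exc.value.sample_index == 1

    def test_learning_updates_weight_matrix(self, short_schedule):
        spec = NetworkSpec(model="berry", n_oscillators=3, weights=0.0005,
                           input_map=(0, 1, 2),
                           learning=ca.HebbianSettings(alpha=-1.0, theta=0.01))
        net = build_network(spec)
        W0 = net.weights.copy()
        net.simulate_clamped([[0.08, 0.02, 0.05]], short_schedule)
        W = net.weights
        assert not np.array_equal(W, W0)
        # the rule is antisymmetric at every instant
        assert np.allclose(W + W.T, 0.0, atol=1e-15)
        assert np.all(np.abs(W) <= 0.01 * max(1.0, np.exp(-1.0)) + 1e-15)
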