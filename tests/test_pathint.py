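"""Path-integration circuit: gating, accumulation, decoding, calibration,
homing, and agreement with the Cartesian summation oracle."""

import time

import numpy as np
import pytest

from antnav import (
    PIParams,
    VectorReadout,
    calibrate_metric_scale,
    cosine_kernel,
    decode_memory,
    encode_heading,
    estimate_position,
    gate_speed,
    homing_command,
    memory_update,
    pi_step,
    preferred_directions,
    reset_state,
)


def script_path(params, headings, steps_per_leg, s=1.0):
    """Drive the circuit along scripted legs; returns the final state."""
    state = reset_state(params)
    for h, n in zip(headings, steps_per_leg):
        for _ in range(n):
            state = pi_step(state, h, s, params)
    return state


class TestGateSpeed:
    def test_speed_modulation(self):
        hd = np.array([1.0, 0.0, -1.0, 0.0])
        assert np.allclose(gate_speed(hd, 0.0), 0.0)
        assert np.allclose(gate_speed(hd, 1.0), [1, 0, 0, 0])
        assert np.allclose(gate_speed(hd, 0.5), [0.5, 0, 0, 0])

    def test_out_of_range_speed_clamped_with_warning(self):
        hd = np.array([1.0, 0.0, -1.0, 0.0])
        with pytest.warns(UserWarning):
            out = gate_speed(hd, 1.5)
        assert np.allclose(out, gate_speed(hd, 1.0))


class TestMemoryUpdate:
    def test_accumulation_rules(self):
        g = np.array([0.5, 0, 0, 0])
        assert np.allclose(memory_update(np.zeros(4), g, 0.3), g)
        assert np.allclose(memory_update(np.array([2.0, 1, 0, 0]), g, 1.0), g)
        mem = np.zeros(4)
        for _ in range(10):
            mem = memory_update(mem, g, 0.0)
        assert np.allclose(mem, [5.0, 0, 0, 0])


class TestDecodeMemory:
    def test_single_direction_and_uniform(self):
        d = preferred_directions(4)
        k = cosine_kernel(d)
        assert np.allclose(decode_memory(np.array([3.0, 0, 0, 0]), k), [3, 0, 0, 0])
        assert np.allclose(decode_memory(np.ones(4), k), 0.0)

    def test_opposite_legs_cancel(self, pi18):
        """5 m east then 5 m west leaves (almost) no decoded vector."""
        n = int(round(5.0 / 0.05))
        state = script_path(pi18, [0.0, np.pi], [n, n], s=1.0)
        peak_state = script_path(pi18, [0.0], [n])
        assert state.decoded.max() < 1e-6 * peak_state.decoded.max()


class TestPiStep:
    def test_straight_east_reads_east(self, pi18):
        state = reset_state(pi18)
        for _ in range(100):
            state = pi_step(state, 0.0, 1.0, pi18)
        assert state.readout.defined
        assert state.readout.angle == pytest.approx(0.0, abs=1e-9)

    def test_square_path_closure(self, pi18):
        """A closed 4 x 5 m square suppresses the output to zero."""
        t0 = time.time()
        n = int(round(5.0 / 0.05))
        headings = np.deg2rad([180.0, 270.0, 0.0, 90.0])
        state = reset_state(pi18)
        peak = 0.0
        for h in headings:
            for _ in range(n):
                state = pi_step(state, h, 1.0, pi18)
                peak = max(peak, state.readout.length)
        assert state.readout.length < 1e-4 * peak
        assert not state.readout.defined or state.readout.length < 1e-4 * peak
        assert time.time() - t0 < 1.0

    def test_zero_speed_freezes_readout(self, pi18):
        state = script_path(pi18, [1.0], [50])
        before = state.readout
        for _ in range(20):
            state = pi_step(state, 2.0, 0.0, pi18)
        assert state.readout.angle == pytest.approx(before.angle)
        assert state.readout.length == pytest.approx(before.length)


class TestResetState:
    def test_reset_is_cold_start(self, pi18):
        state = reset_state(pi18)
        assert state.readout.length == 0.0 and not state.readout.defined
        a = pi_step(reset_state(pi18), 0.3, 1.0, pi18)
        b = pi_step(reset_state(pi18), 0.3, 1.0, pi18)
        assert np.allclose(a.memory, b.memory)


class TestCalibration:
    def test_heading_independent(self, pi18):
        c = calibrate_metric_scale(pi18, 0.05, leg_m=10.0)
        assert c.kappa > 0  # CV < 1% enforced internally

    def test_linear_in_leg_length(self, pi18):
        c5 = calibrate_metric_scale(pi18, 0.05, leg_m=5.0)
        c10 = calibrate_metric_scale(pi18, 0.05, leg_m=10.0)
        assert c5.kappa == pytest.approx(c10.kappa, rel=0.01)

    def test_leak_shrinks_readout(self, pi18):
        kappas = []
        for leak in (0.0, 0.0025, 0.0075, 0.02):
            p = PIParams(n_neurons=18, leak=leak)
            kappas.append(calibrate_metric_scale(p, 0.05, leg_m=10.0).kappa)
        assert np.all(np.diff(kappas) > 0)  # stronger leak -> larger kappa


class TestEstimatePosition:
    def test_round_trip_straight_leg(self, pi18, calib18):
        n = int(round(10.0 / calib18.step_len))
        state = script_path(pi18, [0.0], [n], s=1.0)
        xy = estimate_position(state, calib18)
        assert np.allclose(xy, [n * calib18.step_len, 0.0], atol=0.05)

    def test_zero_state_is_origin(self, pi18, calib18):
        assert np.allclose(estimate_position(reset_state(pi18), calib18), 0.0)

    def test_closed_square_returns_to_origin(self, pi18, calib18):
        n = int(round(5.0 / calib18.step_len))
        state = script_path(pi18, np.deg2rad([180, 270, 0, 90]), [n] * 4)
        assert np.hypot(*estimate_position(state, calib18)) < 0.05


class TestHomingCommand:
    def test_fixed_points(self):
        ro = VectorReadout(angle=0.0, length=1.0)
        assert homing_command(ro, np.pi) == pytest.approx(0.0, abs=1e-12)
        assert homing_command(ro, np.pi / 2) == pytest.approx(1.0)  # left turn home
        assert homing_command(VectorReadout(0.0, 0.0, defined=False), 1.0) == 0.0

    @pytest.mark.parametrize("theta", [0.0, 1.0, 4.0])
    def test_heading_converges_to_inverted_vector(self, theta):
        """Iterating the sine compensation turns the agent to theta - pi."""
        ro = VectorReadout(angle=theta, length=2.0)
        for phi0 in np.linspace(0, 2 * np.pi, 7, endpoint=False):
            if abs(np.angle(np.exp(1j * (phi0 - theta)))) < 1e-9:
                continue  # the unstable fixed point itself
            phi = phi0
            for _ in range(500):
                phi += 0.1 * np.clip(homing_command(ro, phi), -np.pi, np.pi)
            err = np.angle(np.exp(1j * (phi - (theta - np.pi))))
            assert abs(err) < 1e-6

    def test_outward_heading_is_repelling(self):
        theta = 1.0
        ro = VectorReadout(angle=theta, length=2.0)
        phi = theta + 1e-6
        for _ in range(400):
            phi += 0.1 * np.clip(homing_command(ro, phi), -np.pi, np.pi)
        assert abs(np.angle(np.exp(1j * (phi - theta)))) > 0.5


class TestOracleEquivalence:
    def test_matches_cartesian_summation(self, pi18, calib18, rng):
        """Zero noise, leak 0: the circuit equals direct vector summation.

        Run at the walking speed s = 1 used by the closed-loop agent: the
        rectified-cosine speed gate is nonlinear in s (its support narrows
        with speed), so the metric scale is defined at the operating speed.
        """
        for _ in range(5):
            n = 1000
            headings = np.cumsum(rng.normal(0, 0.3, n)) % (2 * np.pi)
            state = reset_state(pi18)
            truth = np.zeros(2)
            path_len = 0.0
            for h in headings:
                state = pi_step(state, h, 1.0, pi18)
                truth += calib18.step_len * np.array([np.cos(h), np.sin(h)])
                path_len += calib18.step_len
            est = estimate_position(state, calib18)
            assert np.hypot(*(est - truth)) < 0.01 * path_len
            ang_err = np.angle(
                np.exp(1j * (np.arctan2(est[1], est[0]) - np.arctan2(truth[1], truth[0])))
            )
            assert abs(ang_err) < np.deg2rad(1.0)
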