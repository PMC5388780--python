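"""Agent kinematics, noise injection, environments and the trial state machine."""

import numpy as np
import pytest

from antnav import (
    AgentState,
    Environment,
    ExplorationState,
    GVMemory,
    NoiseModel,
    TrialProtocol,
    agent_step,
    apply_noise,
    calibrate_metric_scale,
    pi_step,
    reset_state,
    run_trial,
    sample_feeder_positions,
)
from antnav.ring import encode_heading, preferred_directions


class TestApplyNoise:
    def test_zero_noise_is_identity(self, rng):
        d = preferred_directions(18)
        hd = encode_heading(0.3, d)
        phi2, hd2 = apply_noise(0.3, hd, NoiseModel(), rng)
        assert phi2 == 0.3 and np.array_equal(hd2, hd)

    def test_sensory_level_parameterization(self):
        """5% sensory noise means an 18-degree heading SD, exactly."""
        assert np.rad2deg(NoiseModel(zeta_sens=0.05).heading_sd) == pytest.approx(18.0)

    def test_sensory_sd_monte_carlo(self):
        rng = np.random.default_rng(3)
        model = NoiseModel(zeta_sens=0.05)
        phi = np.zeros(100_000)
        phi2, _ = apply_noise(phi, np.zeros((1, 18)), model, rng)
        assert phi2.std() == pytest.approx(model.heading_sd, rel=0.02)

    def test_neural_noise_per_neuron_sd(self):
        rng = np.random.default_rng(4)
        model = NoiseModel(zeta_neur=0.02)
        hd = np.zeros((100_000, 18))
        _, hd2 = apply_noise(0.0, hd, model, rng)
        assert hd2.std(axis=0) == pytest.approx(0.02, rel=0.05)
        # fluctuations are independent across neurons
        corr = np.corrcoef(hd2[:, 0], hd2[:, 1])[0, 1]
        assert abs(corr) < 0.02


class TestAgentStep:
    def test_straight_step(self, kin):
        a = AgentState(heading=0.0)
        b = agent_step(a, 0.0, kin, dt=0.1)
        assert np.allclose(b.position, [kin.step_len, 0.0])

    def test_turn_rate_capped(self, kin):
        a = AgentState(heading=0.0)
        b = agent_step(a, 1e6, kin, dt=0.1)
        assert b.heading == pytest.approx(kin.max_turn_rate * 0.1)

    def test_two_step_geometry(self, kin):
        """Constant turn rate traces a circular arc of radius v/omega."""
        omega = 1.0
        a = AgentState(heading=0.0)
        for _ in range(2):
            a = agent_step(a, omega, kin, dt=0.1)
        expected = kin.step_len * np.array(
            [np.cos(0.1) + np.cos(0.2), np.sin(0.1) + np.sin(0.2)]
        )
        assert np.allclose(a.position, expected)


class TestFeederSampling:
    def test_radius_uniform_not_area_uniform(self):
        rng = np.random.default_rng(5)
        xy = sample_feeder_positions(10_000, 1.0, 40.0, rng)
        r = np.hypot(xy[:, 0], xy[:, 1])
        assert r.min() >= 1.0 and r.max() <= 40.0
        assert r.mean() == pytest.approx(20.5, abs=0.4)  # uniform-radius mean
        th = np.arctan2(xy[:, 1], xy[:, 0])
        assert abs(np.exp(1j * th).mean()) < 0.03  # angles uniform

    def test_bad_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_feeder_positions(5, 2.0, 1.0, rng)


class TestCorrelatedRandomWalk:
    def test_msd_matches_closed_form(self, pi18, kin, calib18):
        """Naive outbound walk obeys the CRW mean-squared-displacement law.

        Per-step heading increments are N(0, dt) (turn rate N(0,1) rad/s at
        eps=1, integrated over dt), so c = E[cos d_phi] = exp(-dt^2/2).
        """
        from antnav import simulate

        n = 2000
        res = simulate(
            envs=Environment(),
            protocol=TrialProtocol(t_forage=n * 0.1, total_time=n * 0.1 + 0.2),
            pi_params=pi18,
            kin=kin,
            noise=NoiseModel(),
            calib=calib18,
            rng=np.random.default_rng(11),
            n_agents=1500,
            n_trials=1,
        )
        d = res.trials.outbound_distance.to_numpy()
        msd = np.mean(d**2)
        c = np.exp(-0.1**2 / 2)
        l = kin.step_len
        expected = l**2 * (
            n * (1 + c) / (1 - c) - 2 * c * (1 - c**n) / (1 - c) ** 2
        )
        assert msd == pytest.approx(expected, rel=0.05)


class TestTrialStateMachine:
    def _components(self, pi18, kin, calib18):
        return dict(
            pi_state=reset_state(pi18),
            gv_mem=GVMemory.naive(18),
            expl_state=ExplorationState(),
            noise=NoiseModel(),
            pi_params=pi18,
            kin=kin,
            calib=calib18,
        )

    def test_nearby_feeder_flips_context_and_scores_goal(self, pi18, kin, calib18):
        rec = run_trial(
            AgentState(heading=0.0),
            Environment.single_feeder(0.1, 0.0),
            TrialProtocol(t_forage=60.0),
            rng=np.random.default_rng(0),
            **self._components(pi18, kin, calib18),
        )
        assert rec.goal_success
        assert rec.homing_success  # feeder sits inside the nest radius
        assert rec.sigma[0] == 1
        assert rec.n_steps < 600  # sated and home within the first minute

    def test_traces_mutually_consistent(self, pi18, kin, calib18):
        rec = run_trial(
            AgentState(heading=1.0),
            Environment.single_feeder(0.5, 1.0),
            TrialProtocol(t_forage=100.0),
            rng=np.random.default_rng(1),
            record_weights=True,
            **self._components(pi18, kin, calib18),
        )
        inward = rec.sigma == 0
        assert np.all(rec.eps[inward] == 0.0)  # eps = 0 whenever sigma = 0
        if inward.any():
            w_in = rec.gv_weights[inward]
            assert np.allclose(w_in, w_in[0])  # weights frozen inbound
        assert np.all(np.diff(rec.beta) > 0)  # beta strictly increasing

    def test_preloaded_vector_gives_straight_goal_run(self, pi18, kin, calib18):
        """With an exact GV and no exploration the agent beelines to the feeder."""
        feeder = np.array([2.0, 0.0])
        state = reset_state(pi18)
        n = int(round(2.0 / kin.step_len))
        for _ in range(n):
            state = pi_step(state, 0.0, 1.0, pi18)
        comps = self._components(pi18, kin, calib18)
        comps["gv_mem"] = GVMemory(weights=state.decoded.copy())
        comps["expl_state"] = ExplorationState(v=1e4)  # eps ~ 0
        rec = run_trial(
            AgentState(heading=0.0),
            Environment(feeders=feeder[None, :]),
            TrialProtocol(t_forage=200.0),
            rng=np.random.default_rng(2),
            **comps,
        )
        assert rec.goal_success
        # en-route headings point at the feeder (after the initial turn-in)
        en_route = (np.hypot(*rec.trajectory.T) > 0.3) & (
            np.hypot(*(rec.trajectory - feeder).T) > 0.5
        ) & (rec.sigma == 1)
        bearings = np.arctan2(
            feeder[1] - rec.trajectory[en_route, 1],
            feeder[0] - rec.trajectory[en_route, 0],
        )
        err = np.rad2deg(np.abs(np.angle(np.exp(1j * (rec.heading[en_route] - bearings)))))
        assert np.median(err) < 5.0

    def test_zero_noise_homing_time_bound(self, pi18, kin, calib18):
        """Inward control reaches the nest in < 2x the beeline time."""
        for dist, theta in ((5.0, 0.3), (15.0, 2.0)):
            state = reset_state(pi18)
            n = int(round(dist / kin.step_len))
            for _ in range(n):
                state = pi_step(state, theta, 1.0, pi18)
            # start heading offset from the outward bearing: the outward
            # direction is the unstable fixed point of the homing dynamics
            agent = AgentState(
                position=dist * np.array([np.cos(theta), np.sin(theta)]),
                heading=theta + 0.5,
            )
            steps = 0
            max_steps = int(2 * dist / kin.step_len)
            while np.hypot(*agent.position) >= 0.2 and steps < max_steps:
                m_hv = kin.turn_gain * calib18.kappa * state.readout.length * np.sin(
                    state.readout.angle - agent.heading - np.pi
                )
                agent = agent_step(agent, m_hv, kin, dt=0.1)
                state = pi_step(state, agent.heading, 1.0, pi18)
                steps += 1
            assert np.hypot(*agent.position) < 0.2
            assert steps < max_steps
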