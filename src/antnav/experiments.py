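"""Scripted experiments: accuracy sweeps, systematic errors, vector learning.

Each runner builds its inputs internally (the model is its own data source),
executes the closed-loop engine and returns an :class:`ExperimentResult`
holding a tidy per-trial DataFrame plus recomputable aggregates.  Every
runner takes an explicit integer seed; per-condition substreams are derived
deterministically from it, so a (config, seed) pair reproduces the result
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent import Environment, KinematicsParams, NoiseModel, TrialProtocol, sample_feeder_positions
from .explore import ExplorationState
from .pathint import PIParams, calibrate_metric_scale, MetricCalibration
from .ring import cosine_kernel, population_phasor, preferred_directions
from .sim import simulate

__all__ = [
    "ExperimentResult",
    "run_pi_accuracy",
    "run_systematic_error",
    "run_gv_single_feeder",
    "run_gv_random_environments",
]


@dataclass
class ExperimentResult:
    """Condition descriptors, per-trial metrics and their aggregates."""

    name: str
    trials: pd.DataFrame
    summary: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _noise_calibration(
    pi_params: PIParams, kin: KinematicsParams, noise: NoiseModel, rng
) -> MetricCalibration:
    """Metric scale measured under the experiment's own noise model.

    Heading noise shrinks the expected decoded vector length by the mean
    resultant of the noise distribution; calibrating under matched noise
    keeps the position estimate unbiased.  Neural noise leaves the scale
    essentially unchanged but is included for symmetry.
    """
    return calibrate_metric_scale(
        pi_params,
        kin.step_len,
        noise_sd=noise.heading_sd,
        n_reps=64 if noise.zeta_sens > 0 else 1,
        rng=rng,
    )


def run_pi_accuracy(
    noise_levels=(0.0, 0.01, 0.02, 0.05),
    noise_kind: str = "sensory",
    n_list=(18,),
    n_trials: int = 1000,
    t_forage: float = 1000.0,
    seed: int = 0,
    kin: KinematicsParams | None = None,
    dt: float = 0.1,
) -> ExperimentResult:
    """Positional accuracy of pure path integration under noise.

    For each (noise level, neuron count): ``n_trials`` independent agents
    forage randomly (no feeders, exploration rate 1) for ``t_forage`` s,
    then switch inward and home by path integration alone.  The per-trial
    metric is the time-averaged distance between the calibrated position
    estimate and the true position over all steps of the trial; the summary
    reports its mean and SD across trials, plus outbound displacement and
    homing success.
    """
    if noise_kind not in ("sensory", "neural"):
        raise ValueError("noise_kind must be 'sensory' or 'neural'")
    kin = kin or KinematicsParams()
    conditions = [(z, n) for z in noise_levels for n in n_list]
    rngs = _spawn(seed, 2 * len(conditions))
    frames = []
    for i, (zeta, n_neurons) in enumerate(conditions):
        noise = (
            NoiseModel(zeta_sens=zeta)
            if noise_kind == "sensory"
            else NoiseModel(zeta_neur=zeta)
        )
        pi_params = PIParams(n_neurons=n_neurons, dt=dt)
        calib = _noise_calibration(pi_params, kin, noise, rngs[2 * i])
        res = simulate(
            envs=Environment(),
            protocol=TrialProtocol(t_forage=t_forage),
            pi_params=pi_params,
            kin=kin,
            noise=noise,
            calib=calib,
            rng=rngs[2 * i + 1],
            n_agents=n_trials,
            n_trials=1,
        )
        df = res.trials.copy()
        df["noise_level"] = zeta
        df["noise_kind"] = noise_kind
        df["n_neurons"] = n_neurons
        frames.append(df)
    trials = pd.concat(frames, ignore_index=True)
    summary = (
        trials.groupby(["noise_kind", "noise_level", "n_neurons"])
        .agg(
            mean_error=("mean_position_error", "mean"),
            sd_error=("mean_position_error", "std"),
            mean_outbound=("outbound_distance", "mean"),
            sd_outbound=("outbound_distance", "std"),
            homing_rate=("homing_success", "mean"),
            n=("mean_position_error", "size"),
        )
        .reset_index()
    )
    return ExperimentResult(
        name="pi_accuracy",
        trials=trials,
        summary=summary,
        seed=seed,
        params=dict(
            noise_levels=list(noise_levels), noise_kind=noise_kind,
            n_list=list(n_list), n_trials=n_trials, t_forage=t_forage,
        ),
    )


def run_systematic_error(
    leak: float = 0.0075,
    alpha_grid_deg: np.ndarray | None = None,
    leg1_m: float = 10.0,
    leg2_m: float = 5.0,
    step_len: float = 0.1,
    n_neurons: int = 18,
    seed: int = 0,
) -> ExperimentResult:
    """Systematic homing error after an L-shaped (two-channel) course.

    The trajectory is scripted (no noise, no closed loop): the agent runs
    ``leg1_m`` metres at heading 0, then ``leg2_m`` metres at heading
    ``alpha``, emulating an ant guided through two straight channels at
    running speed (``step_len`` metres per timestep; the default 0.1 = 1 m/s
    keeps the leak per metre small enough that the first leg always
    dominates the remembered path).  The
    reported quantity is the signed angular error ``delta_theta`` between
    the decoded home direction (theta_HV - pi) and the true home direction,
    per channel angle.  With a leaky integrator (leak > 0) early path
    segments are partly forgotten, biasing the home vector toward the
    recent leg — the signature systematic error; an exact integrator
    (leak = 0) shows none.
    """
    if alpha_grid_deg is None:
        alpha_grid_deg = np.arange(-180.0, 180.1, 2.5)
    alpha = np.deg2rad(np.asarray(alpha_grid_deg, dtype=float))
    params = PIParams(n_neurons=n_neurons, leak=leak)
    dirs = preferred_directions(n_neurons)
    kernel = cosine_kernel(dirs)
    n1 = int(round(leg1_m / step_len))
    n2 = int(round(leg2_m / step_len))
    B = alpha.size
    mem = np.zeros((B, n_neurons))
    for _ in range(n1):
        hd = np.cos(0.0 - dirs)  # heading 0 for every alpha
        mem = np.maximum(0.0, np.maximum(0.0, hd) + (1.0 - leak) * mem)
    for _ in range(n2):
        hd = np.cos(alpha[:, None] - dirs)
        mem = np.maximum(0.0, np.maximum(0.0, hd) + (1.0 - leak) * mem)
    decoded = np.maximum(0.0, mem @ kernel.T)
    th_hv, _ = population_phasor(decoded, dirs)
    end = np.stack(
        [leg1_m + leg2_m * np.cos(alpha), leg2_m * np.sin(alpha)], axis=-1
    )
    true_home = np.arctan2(-end[:, 1], -end[:, 0])
    decoded_home = th_hv - np.pi
    delta = np.angle(np.exp(1j * (decoded_home - true_home)))
    trials = pd.DataFrame(
        {
            "alpha_deg": alpha_grid_deg,
            "delta_theta_deg": np.rad2deg(delta),
            "leak": leak,
        }
    )
    summary = pd.DataFrame(
        {
            "leak": [leak],
            "max_abs_delta_deg": [float(np.max(np.abs(trials.delta_theta_deg)))],
            "delta_at_0": [float(trials.delta_theta_deg.iloc[np.argmin(np.abs(alpha_grid_deg))])],
        }
    )
    return ExperimentResult(
        name="systematic_error",
        trials=trials,
        summary=summary,
        seed=seed,
        params=dict(leak=leak, leg1_m=leg1_m, leg2_m=leg2_m, step_len=step_len),
    )


def run_gv_single_feeder(
    feeder_distance: float = 10.0,
    feeder_angle_deg: float = 90.0,
    t_forage: float = 2000.0,
    n_trials: int = 5,
    zeta_sens: float = 0.05,
    n_neurons: int = 18,
    seed: int = 0,
    kin: KinematicsParams | None = None,
) -> ExperimentResult:
    """Learning walks toward a single feeder (vector-memory acquisition).

    One agent runs ``n_trials`` consecutive trials with a feeder at the
    given distance and bearing.  The global-vector weights and exploration
    state persist across trials; the per-trial rows report the decoded GV
    angle/length, exploration rate and success flags, so the acquisition of
    the vector memory can be followed trial by trial.
    """
    kin = kin or KinematicsParams()
    pi_params = PIParams(n_neurons=n_neurons)
    noise = NoiseModel(zeta_sens=zeta_sens)
    rng_cal, rng_sim = _spawn(seed, 2)
    calib = _noise_calibration(pi_params, kin, noise, rng_cal)
    env = Environment.single_feeder(feeder_distance, np.deg2rad(feeder_angle_deg))
    res = simulate(
        envs=[env],
        protocol=TrialProtocol(t_forage=t_forage),
        pi_params=pi_params,
        kin=kin,
        noise=noise,
        calib=calib,
        rng=rng_sim,
        n_agents=1,
        n_trials=n_trials,
        record_traces=True,
        record_weights=True,
    )
    trials = res.trials.copy()
    trials["gv_angle_deg"] = np.rad2deg(trials.gv_angle)
    trials["feeder_distance"] = feeder_distance
    trials["feeder_angle_deg"] = feeder_angle_deg
    summary = trials[
        ["trial", "goal_success", "homing_success", "mean_eps_outward",
         "gv_length_m", "gv_angle_deg"]
    ].copy()
    result = ExperimentResult(
        name="gv_single_feeder",
        trials=trials,
        summary=summary,
        seed=seed,
        params=dict(
            feeder_distance=feeder_distance, feeder_angle_deg=feeder_angle_deg,
            t_forage=t_forage, n_trials=n_trials, zeta_sens=zeta_sens,
        ),
    )
    result.params["traces"] = res.traces
    return result


def run_gv_random_environments(
    n_cycles: int = 100,
    n_trials: int = 100,
    n_feeders: int = 50,
    r_min: float = 1.0,
    r_max: float = 40.0,
    t_forage: float = 1000.0,
    zeta_sens: float = 0.05,
    n_neurons: int = 18,
    seed: int = 0,
    kin: KinematicsParams | None = None,
) -> ExperimentResult:
    """Vector learning in randomly generated multi-feeder environments.

    Each learning cycle draws a fresh environment of ``n_feeders`` feeders
    (radius uniform on [r_min, r_max], angle uniform) and runs ``n_trials``
    consecutive trials with persistent learning state.  The summary gives,
    per trial index, the mean exploration rate, goal-success and homing
    rates across cycles, plus the ratio of learned-vector length to the
    nearest feeder distance — the quantities that show when and how well
    learning converges.
    """
    kin = kin or KinematicsParams()
    pi_params = PIParams(n_neurons=n_neurons)
    noise = NoiseModel(zeta_sens=zeta_sens)
    rngs = _spawn(seed, 3)
    calib = _noise_calibration(pi_params, kin, noise, rngs[0])
    envs = [
        Environment(feeders=sample_feeder_positions(n_feeders, r_min, r_max, rngs[1]))
        for _ in range(n_cycles)
    ]
    res = simulate(
        envs=envs,
        protocol=TrialProtocol(t_forage=t_forage),
        pi_params=pi_params,
        kin=kin,
        noise=noise,
        calib=calib,
        rng=rngs[2],
        n_agents=n_cycles,
        n_trials=n_trials,
    )
    trials = res.trials.rename(columns={"agent": "cycle"})
    trials["gv_nearest_ratio"] = trials.gv_length_m / trials.nearest_feeder_m
    per_trial = (
        trials.groupby("trial")
        .agg(
            mean_eps=("mean_eps_outward", "mean"),
            goal_rate=("goal_success", "mean"),
            homing_rate=("homing_success", "mean"),
            mean_gv_nearest_ratio=("gv_nearest_ratio", "mean"),
        )
        .reset_index()
    )
    return ExperimentResult(
        name="gv_random_environments",
        trials=trials,
        summary=per_trial,
        seed=seed,
        params=dict(
            n_cycles=n_cycles, n_trials=n_trials, n_feeders=n_feeders,
            r_min=r_min, r_max=r_max, t_forage=t_forage, zeta_sens=zeta_sens,
        ),
    )
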