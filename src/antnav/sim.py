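"""Closed-loop trial engine.

One vectorized engine advances a batch of independent agents (trials or
learning cycles) through the full sensorimotor loop:

    act (from the previous compass sample) -> move -> sense -> path-integrate
    -> collect reward -> learn GV weights -> update reward estimate and
    inverse temperature -> bookkeeping (context switch, trial end).

Each batch element runs its own sequence of ``n_trials`` consecutive trials:
at a trial's end the path integrator and position are reset and a fresh
uniform heading is drawn, while the global-vector memory and the exploration
state persist — learning accumulates across trials within a cycle.

``run_trial`` is the single-agent convenience wrapper returning a full
:class:`~antnav.agent.TrialRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agent import (
    AgentState,
    Environment,
    KinematicsParams,
    NoiseModel,
    TrialProtocol,
    TrialRecord,
)
from .explore import ExplorationState
from .gv import GVMemory, MU_GV
from .pathint import MetricCalibration, PIParams, PIState
from .ring import population_phasor, preferred_directions, cosine_kernel

__all__ = ["SimulationDiverged", "SimResult", "simulate", "run_trial"]

_NAN_CHECK_EVERY = 256


class SimulationDiverged(RuntimeError):
    """Raised when a NaN/Inf appears in the simulation state."""


@dataclass
class SimResult:
    """Batched simulation output.

    trials : tidy DataFrame, one row per (agent, trial).
    traces : per-step traces (only recorded for single-agent runs).
    gv_weights, v, beta : final persistent state per agent, for chaining.
    """

    trials: pd.DataFrame
    traces: dict | None
    gv_weights: np.ndarray
    v: np.ndarray
    beta: np.ndarray


def simulate(
    *,
    envs: list[Environment] | Environment,
    protocol: TrialProtocol,
    pi_params: PIParams,
    kin: KinematicsParams,
    noise: NoiseModel,
    calib: MetricCalibration,
    rng: np.random.Generator,
    n_agents: int = 1,
    n_trials: int = 1,
    gv_weights: np.ndarray | None = None,
    expl: ExplorationState | None = None,
    mu_gv: float = MU_GV,
    init_heading: np.ndarray | None = None,
    init_memory: np.ndarray | None = None,
    record_traces: bool = False,
    record_weights: bool = False,
) -> SimResult:
    """Run ``n_agents`` independent agents for ``n_trials`` trials each."""
    if isinstance(envs, Environment):
        envs = [envs] * n_agents
    if len(envs) != n_agents:
        raise ValueError("need one Environment per agent (or a single shared one)")
    if record_traces and n_agents != 1:
        raise ValueError("traces can only be recorded for a single agent")

    B = n_agents
    N = pi_params.n_neurons
    dt = pi_params.dt
    dirs = preferred_directions(N)
    kernel = cosine_kernel(dirs)
    lam = pi_params.leak
    kappa = calib.kappa
    nest_r = envs[0].nest_radius

    n_feed = max(e.feeders.shape[0] for e in envs)
    if n_feed > 0:
        feeders = np.full((B, n_feed, 2), np.inf)
        for b, e in enumerate(envs):
            k = e.feeders.shape[0]
            if k:
                feeders[b, :k] = e.feeders
    else:
        feeders = None

    n_out = int(round(protocol.t_forage / dt))
    n_T = int(round(protocol.total_time / dt))
    thr = protocol.reward_switch_threshold

    expl = expl or ExplorationState(dt=dt)
    gamma_step = expl.gamma_step
    mu_b, mu_v = expl.mu_beta, expl.mu_v

    pos = np.zeros((B, 2))
    phi = (
        np.array(init_heading, dtype=float).reshape(B)
        if init_heading is not None
        else rng.uniform(0.0, 2.0 * np.pi, B)
    )
    phin = phi.copy()
    mem = (
        np.tile(np.asarray(init_memory, dtype=float), (B, 1))
        if init_memory is not None
        else np.zeros((B, N))
    )
    decoded = np.maximum(0.0, mem @ kernel.T)
    th_hv, l_hv = population_phasor(decoded, dirs)
    w = (
        np.tile(np.asarray(gv_weights, dtype=float), (B, 1))
        if gv_weights is not None
        else np.zeros((B, N))
    )
    v = np.full(B, float(expl.v))
    beta = np.full(B, float(expl.beta))
    sigma = np.ones(B)
    racc = np.zeros(B)
    t_tr = np.zeros(B, dtype=np.int64)
    trial = np.zeros(B, dtype=np.int64)
    done = np.zeros(B, dtype=bool)

    eps_sum = np.zeros(B)
    out_steps = np.zeros(B, dtype=np.int64)
    err_sum = np.zeros(B)
    goal = np.zeros(B, dtype=bool)
    out_dist = np.full(B, np.nan)

    rows: list[tuple] = []
    tr: dict[str, list] | None = None
    if record_traces:
        tr = {k: [] for k in ("x", "y", "phi", "sigma", "r", "eps", "beta", "v",
                              "est_x", "est_y", "trial")}
        if record_weights:
            tr["w"] = []

    sens_sd = noise.heading_sd
    step_count = 0
    while not done.all():
        step_count += 1
        active = ~done
        # --- act on the previous compass sample -------------------------------
        eps = sigma * np.exp(-beta * v)
        th_gv, l_gv = population_phasor(np.maximum(w, 0.0), dirs)
        m_gv = kappa * l_gv * np.sin(th_gv - phin)
        m_hv = kappa * l_hv * np.sin(th_hv - phin - np.pi)
        draw = rng.standard_normal(B)
        m_eps = np.where(eps > 0.0, draw * eps, 0.0)
        cmd = (1.0 - eps) * (sigma * m_gv + m_hv) + m_eps
        rate = np.clip(kin.turn_gain * cmd, -kin.max_turn_rate, kin.max_turn_rate)
        phi = (phi + np.where(active, rate * dt, 0.0)) % (2.0 * np.pi)
        step = np.where(active, kin.step_len, 0.0)
        pos[:, 0] += step * np.cos(phi)
        pos[:, 1] += step * np.sin(phi)
        # --- sense ------------------------------------------------------------
        dphi = rng.normal(0.0, sens_sd, B) if sens_sd > 0.0 else 0.0
        phin = phi + dphi
        hd = np.cos(phin[:, None] - dirs)
        if noise.zeta_neur > 0.0:
            hd = hd + rng.normal(0.0, noise.zeta_neur, (B, N))
        # --- path integration (speed s = 1 while walking) ---------------------
        gated = np.maximum(0.0, hd - 1.0 + 1.0)
        mem = np.where(active[:, None], np.maximum(0.0, gated + (1.0 - lam) * mem), mem)
        decoded = np.maximum(0.0, mem @ kernel.T)
        th_hv, l_hv = population_phasor(decoded, dirs)
        est_x = kappa * l_hv * np.cos(th_hv)
        est_y = kappa * l_hv * np.sin(th_hv)
        err = np.hypot(est_x - pos[:, 0], est_y - pos[:, 1])
        # --- reward and learning ----------------------------------------------
        if feeders is not None:
            d = np.min(
                np.hypot(feeders[..., 0] - pos[:, None, 0],
                         feeders[..., 1] - pos[:, None, 1]),
                axis=1,
            )
            r = np.maximum(0.0, 1.0 - 5.0 * d)
        else:
            r = np.zeros(B)
        goal |= (r > 0.0) & active
        upd = active & (sigma > 0.0) & (r > 0.0)
        if upd.any():
            w[upd] += mu_gv * r[upd, None] * (decoded[upd] - w[upd])
        v = np.where(active, r + gamma_step * v, v)
        beta = np.where(active, beta + mu_b * (1.0 / beta + mu_v * v * eps), beta)
        # --- bookkeeping ------------------------------------------------------
        racc += np.where(active, r, 0.0)
        t_tr += active
        outward = active & (sigma > 0.0)
        eps_sum += np.where(outward, eps, 0.0)
        out_steps += outward
        err_sum += np.where(active, err, 0.0)

        if record_traces:
            tr["x"].append(pos[0, 0]); tr["y"].append(pos[0, 1])
            tr["phi"].append(phi[0]); tr["sigma"].append(sigma[0])
            tr["r"].append(r[0]); tr["eps"].append(eps[0])
            tr["beta"].append(beta[0]); tr["v"].append(v[0])
            tr["est_x"].append(est_x[0]); tr["est_y"].append(est_y[0])
            tr["trial"].append(trial[0])
            if record_weights:
                tr["w"].append(w[0].copy())

        flip = active & (sigma > 0.0) & ((racc > thr) | (t_tr >= n_out))
        if flip.any():
            sigma[flip] = 0.0
            out_dist[flip] = np.hypot(pos[flip, 0], pos[flip, 1])

        if step_count % _NAN_CHECK_EVERY == 0:
            if not (np.isfinite(pos[active]).all() and np.isfinite(v[active]).all()
                    and np.isfinite(beta[active]).all()):
                raise SimulationDiverged(
                    f"non-finite state at engine step {step_count}: "
                    f"pos finite={np.isfinite(pos).all()}, "
                    f"v finite={np.isfinite(v).all()}, "
                    f"beta finite={np.isfinite(beta).all()}"
                )

        at_nest = np.hypot(pos[:, 0], pos[:, 1]) < nest_r
        ended = active & (((sigma == 0.0) & at_nest) | (t_tr >= n_T))
        if ended.any():
            idx = np.flatnonzero(ended)
            for b in idx:
                th_g, l_g = population_phasor(np.maximum(w[b], 0.0), dirs)
                if feeders is not None:
                    nearest = float(np.min(np.hypot(feeders[b, :, 0], feeders[b, :, 1])))
                else:
                    nearest = np.nan
                rows.append((
                    b, int(trial[b]), int(t_tr[b]), int(out_steps[b]),
                    float(out_dist[b]),
                    bool(goal[b]), bool(at_nest[b] & (sigma[b] == 0.0)),
                    float(eps_sum[b] / max(out_steps[b], 1)),
                    float(err_sum[b] / max(t_tr[b], 1)),
                    float(kappa * l_g), float(th_g), nearest,
                    float(v[b]), float(beta[b]),
                ))
            trial[idx] += 1
            newly_done = trial[idx] >= n_trials
            done[idx[newly_done]] = True
            live = idx[~newly_done]
            if live.size:
                pos[live] = 0.0
                phi[live] = rng.uniform(0.0, 2.0 * np.pi, live.size)
                phin[live] = phi[live]
                mem[live] = 0.0
                l_hv[live] = 0.0
                sigma[live] = 1.0
                racc[live] = 0.0
                t_tr[live] = 0
                eps_sum[live] = 0.0
                out_steps[live] = 0
                err_sum[live] = 0.0
                goal[live] = False
                out_dist[live] = np.nan

    trials = pd.DataFrame(
        rows,
        columns=[
            "agent", "trial", "n_steps", "outbound_steps", "outbound_distance",
            "goal_success", "homing_success", "mean_eps_outward",
            "mean_position_error", "gv_length_m", "gv_angle",
            "nearest_feeder_m", "v_end", "beta_end",
        ],
    ).sort_values(["agent", "trial"]).reset_index(drop=True)

    traces = None
    if record_traces:
        traces = {k: np.asarray(val) for k, val in tr.items()}
    return SimResult(trials=trials, traces=traces, gv_weights=w, v=v, beta=beta)


def run_trial(
    agent: AgentState,
    env: Environment,
    protocol: TrialProtocol,
    pi_state: PIState,
    gv_mem: GVMemory,
    expl_state: ExplorationState,
    noise: NoiseModel,
    rng: np.random.Generator,
    *,
    pi_params: PIParams | None = None,
    kin: KinematicsParams | None = None,
    calib: MetricCalibration,
    record_weights: bool = False,
) -> TrialRecord:
    """Run one complete foraging trial for a single agent.

    The global-vector memory and exploration state are advanced *in place*
    (they persist across trials of a learning cycle); the path integrator is
    taken from ``pi_state`` and is reset by the caller between trials per the
    protocol.  Returns a :class:`TrialRecord` with full traces.
    """
    pi_params = pi_params or PIParams()
    kin = kin or KinematicsParams()
    res = simulate(
        envs=[env],
        protocol=protocol,
        pi_params=pi_params,
        kin=kin,
        noise=noise,
        calib=calib,
        rng=rng,
        n_agents=1,
        n_trials=1,
        gv_weights=gv_mem.weights,
        expl=expl_state,
        mu_gv=gv_mem.mu,
        init_heading=np.array([agent.heading]),
        init_memory=pi_state.memory,
        record_traces=True,
        record_weights=record_weights,
    )
    gv_mem.weights = res.gv_weights[0]
    expl_state.v = float(res.v[0])
    expl_state.beta = float(res.beta[0])
    t = res.traces
    row = res.trials.iloc[0]
    return TrialRecord(
        trajectory=np.column_stack([t["x"], t["y"]]),
        heading=t["phi"],
        sigma=t["sigma"],
        reward=t["r"],
        eps=t["eps"],
        beta=t["beta"],
        v=t["v"],
        estimate=np.column_stack([t["est_x"], t["est_y"]]),
        goal_success=bool(row.goal_success),
        homing_success=bool(row.homing_success),
        outbound_distance=float(row.outbound_distance),
        mean_position_error=float(row.mean_position_error),
        gv_weights=t.get("w"),
    )
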