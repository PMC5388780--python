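"""Adaptive random search and action selection.

Exploration is a correlated Gaussian random walk whose per-step turning SD is
the exploration rate ``eps = sigma * exp(-beta * v)``: it starts at 1 for a
naive outward agent and collapses as the low-pass reward estimate ``v``
charges up.  The inverse temperature ``beta`` slowly grows (a gradient rule
on the divergence between the current and an optimal exploration
distribution), locking in exploitation.  The final motor command blends the
global-vector and homing signals with the random turn:

    Sigma = (1 - eps) * (sigma * m_GV + m_HV) + m_eps

On inward trips sigma = 0 forces eps = 0 and the command reduces to pure
path-integration homing.

The reward discount ``gamma`` is specified per second of simulated time
(per-step factor ``gamma ** dt``), giving the reward memory a time constant
commensurate with a foraging trip rather than with a single integration step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ExplorationState",
    "update_value",
    "exploration_rate",
    "update_beta",
    "sample_random_turn",
    "select_action",
]


@dataclass
class ExplorationState:
    """Low-pass reward estimate and inverse-temperature state.

    v : discounted reward estimate (dimensionless), >= 0.
    beta : inverse temperature, > 0 and non-decreasing over time.
    gamma : reward discount per *second* of simulated time.
    mu_beta : global learning rate of the beta update.
    mu_v : reward-based learning rate of the beta update.
    dt : timestep, seconds (sets the per-step discount ``gamma ** dt``).
    """

    v: float = 0.0
    beta: float = 1.0
    gamma: float = 0.995
    mu_beta: float = 1e-6
    mu_v: float = 1e2
    dt: float = 0.1

    @property
    def gamma_step(self) -> float:
        return self.gamma ** self.dt

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")


def update_value(state: ExplorationState, r: float) -> ExplorationState:
    """One step of the reward low-pass ``v' = r + gamma_step * v``.

    Applied every timestep, inward and outward alike.
    """
    return replace(state, v=float(r) + state.gamma_step * state.v)


def exploration_rate(state: ExplorationState, sigma: float) -> float:
    """``eps = sigma * exp(-beta * v)``: 1 for a naive outward agent, 0 inward."""
    return float(sigma) * float(np.exp(-state.beta * state.v))


def update_beta(state: ExplorationState, eps: float) -> ExplorationState:
    """Inverse-temperature growth ``beta' = beta + mu_beta (1/beta + mu_v v eps)``.

    Strictly increasing: both terms are nonnegative and 1/beta is positive.
    """
    if state.beta <= 0:
        raise RuntimeError(f"corrupted exploration state: beta={state.beta} <= 0")
    dbeta = state.mu_beta * (1.0 / state.beta + state.mu_v * state.v * eps)
    return replace(state, beta=state.beta + dbeta)


def sample_random_turn(eps, rng: np.random.Generator):
    """Random turn ``m_eps ~ N(0, eps)`` (eps is the SD); exactly 0 at eps = 0.

    Accepts a scalar or an array of exploration rates (one draw each).
    """
    eps = np.asarray(eps, dtype=float)
    draw = rng.standard_normal(eps.shape) * eps
    out = np.where(eps > 0.0, draw, 0.0)
    return float(out) if out.ndim == 0 else out


def select_action(eps, sigma, m_gv, m_hv, m_eps):
    """Blend vector steering and random search into the final turn command."""
    return (1.0 - eps) * (sigma * m_gv + m_hv) + m_eps
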