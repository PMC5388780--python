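"""Global-vector memory: reward-modulated learning of a nest->feeder vector.

A binary foraging-context unit (sigma = 1 outward, 0 inward) projects plastic
synapses ``w_i^GV`` onto a circular array with the same geometry as the
path-integration output.  When food reward arrives, a delta-rule update pulls
the weights toward the current PI activity pattern, so after a visit or two
the weight profile *is* the PI state at the feeder — a population-coded
vector from the nest to the food.  Expression of the memory is gated by the
context unit, and the steering command is sine error compensation toward the
stored direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pathint import MetricCalibration
from .ring import VectorReadout, population_vector

__all__ = [
    "GVMemory",
    "compute_reward",
    "gv_activity",
    "gv_learning_step",
    "gv_readout",
    "gv_command",
]

#: Learning rate mu_GV of the reward-modulated delta rule.
MU_GV = 2.0


@dataclass
class GVMemory:
    """Plastic weight vector of the global-vector array."""

    weights: np.ndarray
    mu: float = MU_GV

    @classmethod
    def naive(cls, n_neurons: int, mu: float = MU_GV) -> "GVMemory":
        return cls(weights=np.zeros(n_neurons), mu=mu)


def compute_reward(d) -> np.ndarray | float:
    """Food reward ``r = max(0, 1 - 5 d)`` for distance ``d`` (metres) to food.

    The reward is physically bound to the feeder: it is positive only within
    0.2 m and peaks at 1 on top of it.  Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance to feeder cannot be negative")
    r = np.maximum(0.0, 1.0 - 5.0 * d)
    return float(r) if r.ndim == 0 else r


def gv_activity(mem: GVMemory, sigma) -> np.ndarray:
    """Array activity ``x_i^GV = w_i^GV * sigma``: silent on inward trips."""
    sigma = np.asarray(sigma, dtype=float)
    return mem.weights * sigma[..., None] if sigma.ndim else mem.weights * float(sigma)


def gv_learning_step(mem: GVMemory, sigma, r, pi_rates: np.ndarray) -> GVMemory:
    """Reward-modulated associative update.

    ``w' = w + mu * r * sigma * (x_PI - x_GV)`` with ``x_GV = w * sigma``.
    No change when the reward is zero or the agent is inbound; the fixed
    point under sustained reward is ``w = x_PI``.  ``mu * r`` can reach 2 at
    the feeder centre (marginally stable overshoot); this is not clamped, but
    an overshooting step is reported via a numpy warning-free check by the
    caller if desired.
    """
    sigma = np.asarray(sigma, dtype=float)
    r = np.asarray(r, dtype=float)
    w = np.asarray(mem.weights, dtype=float)
    gate = (mem.mu * r * sigma)[..., None] if r.ndim or sigma.ndim else mem.mu * float(r) * float(sigma)
    x_gv = w * (sigma[..., None] if sigma.ndim else float(sigma))
    return GVMemory(weights=w + gate * (np.asarray(pi_rates, dtype=float) - x_gv), mu=mem.mu)


def gv_readout(mem: GVMemory, dirs: np.ndarray) -> VectorReadout:
    """Population vector of the stored weights (the learned vector itself)."""
    return population_vector(np.maximum(mem.weights, 0.0), dirs)


def gv_command(readout: VectorReadout, phi: float, calib: MetricCalibration | None = None) -> float:
    """Steering command toward the remembered feeder.

    ``m_GV = l_GV * sin(theta_GV - phi)``; zero for a naive (all-zero) memory.
    If ``calib`` is given the length is converted to metres first, putting the
    command on the same footing as the homing signal.
    """
    if not readout.defined:
        return 0.0
    l = readout.length * (calib.kappa if calib is not None else 1.0)
    return float(l * np.sin(readout.angle - phi))
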