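"""Circular-array population code.

Every layer of the navigation circuit represents a 2-D vector as the firing
pattern of a ring of ``N`` neurons whose preferred directions evenly tile the
circle.  A heading is *encoded* by a cosine tuning curve, and the vector
carried by a (rectified, nonnegative) activity profile is *decoded* by the
population-vector average: the activity-weighted sum of preferred-direction
unit vectors.  The cosine weight kernel connecting two rings extracts exactly
the first circular harmonic of the presynaptic profile, which is why this
coarse code supports accurate vector arithmetic with as few as ~18 neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VectorReadout",
    "preferred_directions",
    "encode_heading",
    "cosine_kernel",
    "population_phasor",
    "population_vector",
]

#: Activity below this total population-vector norm is treated as "no vector".
TOL_ZERO = 1e-9


@dataclass(frozen=True)
class VectorReadout:
    """A (direction, magnitude) pair decoded from a circular array.

    ``defined`` is False when the population activity carries no net vector
    (e.g. the home-vector array of an agent standing at the nest, where
    opposite travel directions cancel); in that case ``length`` is 0 and
    ``angle`` is reported as 0 by convention.
    """

    angle: float
    length: float
    defined: bool = True

    def cartesian(self) -> np.ndarray:
        return self.length * np.array([np.cos(self.angle), np.sin(self.angle)])


def preferred_directions(n: int) -> np.ndarray:
    """Evenly spaced preferred directions ``phi_i = 2*pi*i/N``, i in [0, N-1].

    Raises
    ------
    ValueError
        If ``n < 3`` — two neurons cannot represent a 2-D vector with
        nonnegative rates, and the population vector degenerates.
    """
    if n < 3:
        raise ValueError(
            f"a circular array needs at least 3 neurons, got N={n}: "
            "the population vector is degenerate below that"
        )
    return 2.0 * np.pi * np.arange(n) / n


def encode_heading(phi, dirs: np.ndarray) -> np.ndarray:
    """Cosine head-direction tuning: ``rates_i = cos(phi - phi_i)``.

    ``phi`` may be a scalar or any array; a trailing axis of length ``N`` is
    appended.  The heading is implicitly 2*pi-periodic.
    """
    phi = np.asarray(phi, dtype=float)
    return np.cos(phi[..., None] - dirs)


def cosine_kernel(dirs: np.ndarray) -> np.ndarray:
    """Symmetric decoding kernel ``w_ij = cos(phi_i - phi_j)``.

    Acting on a ring profile it extracts the first circular harmonic
    (each row sums to zero for N >= 3, so uniform activity decodes to nothing).
    """
    return np.cos(dirs[:, None] - dirs[None, :])


def population_phasor(act: np.ndarray, dirs: np.ndarray):
    """Population-vector average of an activity profile, batch-friendly.

    Returns ``(angle, length)`` arrays where ``angle`` is the quadrant-aware
    arctangent of the summed sine/cosine components, wrapped to [0, 2*pi),
    and ``length`` is the Euclidean norm of the summed 2-vector.
    """
    act = np.asarray(act, dtype=float)
    x = act @ np.cos(dirs)
    y = act @ np.sin(dirs)
    return np.arctan2(y, x) % (2.0 * np.pi), np.hypot(x, y)


def population_vector(
    act: np.ndarray, dirs: np.ndarray, tol_zero: float = TOL_ZERO
) -> VectorReadout:
    """Decode a single rectified activity profile into a :class:`VectorReadout`.

    Meant to be called on nonnegative (post-rectification) profiles.  A net
    vector shorter than ``tol_zero`` yields ``defined=False`` with angle and
    length 0 — a legitimate state, not an error: the home-vector array is
    suppressed to zero whenever the agent stands at its estimated origin.
    """
    angle, length = population_phasor(np.asarray(act, dtype=float), dirs)
    if length < tol_zero:
        return VectorReadout(angle=0.0, length=0.0, defined=False)
    return VectorReadout(angle=float(angle), length=float(length), defined=True)
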