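"""Conventional binary PSO update rules.

Per dimension d, a particle keeps a real velocity v^d that is pulled
toward its personal best and the swarm's global best, squashed through a
sigmoid, and compared against a fresh uniform draw to decide the bit:

    v^d <- w * v^d + c1 * r1^d * (pbest^d - x^d) + c2 * r2^d * (gbest^d - x^d)
    x^d <- 1 if Sig(v^d) > r3^d else 0

Velocities are clamped to [-V_max, V_max] with V_max = (1/3) * n by
default, preventing permanently saturated bit probabilities. Because the
standard sigmoid gives P(bit = 1) = 0.5 at v = 0, a swarm over many
dimensions hovers near selecting half of all genes — the weakness the
enhanced variant (see :mod:`swarmselect.epso`) targets.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def standard_sigmoid(v):
    """Logistic transfer function 1 / (1 + e^(-v)), in (0, 1)."""
    return expit(v)


def bpso_velocity_step(velocity, position, pbest, gbest, w, c1, c2, v_max, r1, r2):
    """One velocity update for a single particle, clamped to [-v_max, v_max].

    ``r1`` and ``r2`` are per-dimension uniform draws on [0, 1] (fresh for
    every particle and iteration).
    """
    velocity = np.asarray(velocity, dtype=np.float64)
    position = np.asarray(position)
    pbest = np.asarray(pbest)
    gbest = np.asarray(gbest)
    if not (velocity.shape == position.shape == pbest.shape == gbest.shape):
        raise ValueError("velocity, position, pbest and gbest must share length")
    v = (
        w * velocity
        + c1 * np.asarray(r1) * (pbest.astype(np.float64) - position)
        + c2 * np.asarray(r2) * (gbest.astype(np.float64) - position)
    )
    return np.clip(v, -v_max, v_max)


def bpso_position_step(velocity, r3):
    """Resample bits: bit = 1 iff Sig(v^d) > r3^d, else 0."""
    return (standard_sigmoid(np.asarray(velocity)) > np.asarray(r3)).astype(np.uint8)
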