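"""Enhanced binary PSO rules: scalar particle speed, position distance,
steepened sigmoid, and the inverted bit-update rule.

The enhancement replaces the per-dimension velocity vector with one
non-negative scalar speed s per particle,

    s <- w * s + c1 * r1 * dist(pbest, X) + c2 * r2 * dist(gbest, X),

where dist is a scalar distance between two binary positions (below),
and inverts the bit rule so that a large transfer probability clears
bits instead of setting them:

    x^d <- 0 if Sig(alpha * s) > r3^d else 1.

Since s >= 0 always, Sig(alpha * s) >= 0.5, hence P(bit = 1) <= 0.5 at
every dimension and the swarm is biased toward small gene subsets — the
core sparsity mechanism of the method.

Distance between binary positions
---------------------------------
For best position B and current position X, form diff = B - X
elementwise (values in {-1, 0, +1}); with a = #{+1} (bits the particle
is missing relative to the best) and b = #{-1} (bits it selected
superfluously), the distance is |a - b|. It is non-negative and zero for
identical positions, but it is *not* a metric (|a - b| can be 0 for
different positions and the triangle inequality can fail), and only the
former two properties are relied upon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class PositionDiff:
    """Elementwise difference of two binary positions and its summary.

    Attributes
    ----------
    diff : ndarray in {-1, 0, +1}
        best - position, per dimension.
    a : int
        Count of +1 entries (genes selected by the best but not here).
    b : int
        Count of -1 entries (genes selected here but not by the best).
    distance : int
        |a - b|, the scalar distance used in the speed update.
    """

    diff: np.ndarray
    a: int
    b: int
    distance: int


def position_diff(best, position) -> PositionDiff:
    """Compare a best position against a particle's current position."""
    best = np.asarray(best, dtype=np.int64)
    position = np.asarray(position, dtype=np.int64)
    if best.shape != position.shape:
        raise ValueError("positions must share length")
    diff = best - position
    a = int(np.count_nonzero(diff == 1))
    b = int(np.count_nonzero(diff == -1))
    return PositionDiff(diff=diff, a=a, b=b, distance=abs(a - b))


def epso_speed_step(speed, position, pbest, gbest, w, c1, c2, v_max, r1, r2):
    """One scalar speed update, clamped to [0, v_max].

    ``r1`` and ``r2`` are single uniform draws per particle per iteration
    (the speed is a scalar, so there is no per-dimension randomness here).
    """
    if speed < 0:
        raise ValueError(f"corrupted state: negative incoming speed {speed}")
    s = (
        w * speed
        + c1 * r1 * position_diff(pbest, position).distance
        + c2 * r2 * position_diff(gbest, position).distance
    )
    return float(np.clip(s, 0.0, v_max))


def modified_sigmoid(speed, steepness):
    """Steepened transfer function Sig(alpha * s) = 1 / (1 + e^(-alpha*s)).

    Defined for s >= 0 only, so its value is always >= 0.5: under the
    inverted bit rule this caps P(bit = 1) at 0.5 and pushes it toward 0
    as the speed grows.
    """
    s = np.asarray(speed, dtype=np.float64)
    if np.any(s < 0):
        raise ValueError("speed must be non-negative")
    if steepness <= 0:
        raise ValueError("steepness must be positive")
    out = expit(steepness * s)
    return float(out) if out.ndim == 0 else out


def epso_position_step(speed, r3, steepness, min_set_prob=0.0):
    """Resample bits under the inverted rule: bit = 0 iff Sig(alpha*s) > r3^d.

    The same scalar speed governs every dimension; ``r3`` holds fresh
    per-dimension uniform draws.

    ``min_set_prob`` bounds the per-dimension bit-set probability from
    below (the bit-clear probability becomes
    ``min(Sig(alpha*s), 1 - min_set_prob)``). Without it, a speed pinned
    at a large clamp saturates the sigmoid to exactly 1 in floating
    point and every subsequent position is the empty subset; a small
    floor keeps the bit process ergodic while preserving the strong
    zero bias. 0 gives the literal rule.
    """
    if not 0.0 <= min_set_prob <= 0.5:
        raise ValueError("min_set_prob must lie in [0, 0.5]")
    p_zero = min(modified_sigmoid(speed, steepness), 1.0 - min_set_prob)
    return np.where(p_zero > np.asarray(r3), 0, 1).astype(np.uint8)
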