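"""Swarm configuration: every tunable of the optimizer in one flat record.

Defaults follow the published benchmark protocol for wrapper gene
selection with a binary swarm (100 particles, 500 iterations, c1 = c2 = 2,
fitness weights 0.8 / 0.2) plus the choices this package fixes where the
protocol is silent (initialization distributions, clamps, sigmoid slope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import yaml

#: Default floor on the enhanced rule's per-dimension bit-set probability:
#: Sig(-5), the complement of the steepened sigmoid at its saturation scale.
DEFAULT_MIN_SET_PROB = 1.0 / (1.0 + math.exp(5.0))


@dataclass(frozen=True)
class SwarmConfig:
    """Configuration for a single optimizer run.

    Attributes
    ----------
    num_particles : swarm size m.
    max_iter : iteration (generation) budget; the only stopping rule.
    c1, c2 : acceleration constants, each in [0, 2].
    w_init : initial inertia weight, decayed nonlinearly to ``w_floor``.
    w_floor : inertia asymptote of the decay schedule.
    v_max_fraction : velocity/speed clamp as a fraction of the gene count n
        (V_max = v_max_fraction * n).
    w1, w2 : fitness weights for accuracy and subset-size reward;
        w1 in [0.6, 0.9] and w2 = 1 - w1.
    sigmoid_steepness : slope alpha of the enhanced variant's sigmoid.
    init_bit_prob : probability each bit of an initial position is 1.
    speed_init_range : (low, high]; initial scalar speeds are drawn
        uniformly from this interval (strictly positive by default).
    min_set_prob : floor on the enhanced rule's per-dimension probability
        of setting a bit. The speed's attraction terms scale with the
        position distance (up to n), so the scalar speed pins at its
        clamp and the steepened sigmoid would saturate to exactly 1 in
        floating point, freezing every particle at the empty subset.
        Bounding the transfer probability away from saturation — the
        classic binary-PSO practice of clamping velocities at +/-4..6 so
        bit-flip probabilities never vanish — keeps the bit process
        ergodic. Default Sig(-5) ~= 0.00669, the bit-set probability at
        the sigmoid's saturation scale; set to 0 for the literal rule.
    seed : master seed; equal seeds give bit-identical runs.
    """

    num_particles: int = 100
    max_iter: int = 500
    c1: float = 2.0
    c2: float = 2.0
    w_init: float = 1.4
    w_floor: float = 0.4
    v_max_fraction: float = 1.0 / 3.0
    w1: float = 0.8
    w2: float = 0.2
    sigmoid_steepness: float = 5.0
    init_bit_prob: float = 0.5
    speed_init_range: tuple = (0.0, 1.0)
    min_set_prob: float = DEFAULT_MIN_SET_PROB
    seed: int = 0

    def __post_init__(self):
        if self.num_particles < 1:
            raise ValueError("num_particles must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        for name in ("c1", "c2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 2.0:
                raise ValueError(f"{name} must lie in [0, 2], got {v}")
        if not 0.6 <= self.w1 <= 0.9:
            raise ValueError(f"w1 must lie in [0.6, 0.9], got {self.w1}")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("w2 must equal 1 - w1")
        if self.v_max_fraction <= 0:
            raise ValueError("v_max_fraction must be positive")
        if self.sigmoid_steepness <= 0:
            raise ValueError("sigmoid_steepness must be positive")
        if not 0.0 <= self.init_bit_prob <= 1.0:
            raise ValueError("init_bit_prob must lie in [0, 1]")
        lo, hi = self.speed_init_range
        if not (0.0 <= lo < hi):
            raise ValueError("speed_init_range must satisfy 0 <= low < high")
        if not 0.0 <= self.min_set_prob <= 0.5:
            raise ValueError("min_set_prob must lie in [0, 0.5]")
        if self.w_floor < 0 or self.w_init < self.w_floor:
            raise ValueError("need 0 <= w_floor <= w_init")

    def v_max(self, n_genes: int) -> float:
        return self.v_max_fraction * n_genes

    def with_(self, **kwargs) -> "SwarmConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["speed_init_range"] = list(self.speed_init_range)
        return d

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "SwarmConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "speed_init_range" in raw:
            raw["speed_init_range"] = tuple(raw["speed_init_range"])
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
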