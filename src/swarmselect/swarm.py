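"""Swarm state and the main optimization loop shared by both variants.

Loop order per iteration: evaluate every particle's fitness, update
personal/global bests, update the inertia weight, then move particles
under the variant's rules. The iteration budget is the only stopping
rule — no early stopping and no global-best resets.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bpso import bpso_position_step, bpso_velocity_step
from .config import SwarmConfig
from .dataset import ExpressionDataset
from .epso import epso_position_step, epso_speed_step
from .fitness import FitnessEvaluator

VARIANTS = ("bpso", "epso")


def random_stream(seed: int) -> np.random.Generator:
    """The package's single source of uniform draws (PCG64)."""
    return np.random.default_rng(seed)


def update_inertia(w_current: float, iteration: int, config: SwarmConfig) -> float:
    """Nonlinear decreasing inertia recurrence.

    w(t+1) = (w(t) - w_floor) * (max_iter - t) / max_iter + w_floor,
    applied once per iteration so repeated application decays w from
    ``w_init`` toward ``w_floor`` faster than a linear ramp.
    """
    if config.max_iter <= 0:
        raise ValueError("max_iter must be positive")
    if not 0 <= iteration <= config.max_iter:
        raise ValueError("iteration out of range")
    if w_current < config.w_floor:
        raise ValueError("inertia below its floor")
    frac = (config.max_iter - iteration) / config.max_iter
    return (w_current - config.w_floor) * frac + config.w_floor


@dataclass
class Swarm:
    """Mutable optimizer state for one run."""

    variant: str
    positions: np.ndarray            # (m, n) uint8
    pbest_positions: np.ndarray      # (m, n) uint8
    pbest_fitness: np.ndarray        # (m,)
    pbest_accuracy: np.ndarray       # (m,)
    velocities: np.ndarray = None    # (m, n), BPSO only
    speeds: np.ndarray = None        # (m,), EPSO only

    @property
    def num_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_genes(self) -> int:
        return self.positions.shape[1]


def initialize_swarm(n: int, config: SwarmConfig, rng: np.random.Generator,
                     variant: str) -> Swarm:
    """Draw initial positions and motion state.

    Bits are independent Bernoulli(init_bit_prob); BPSO velocities are
    uniform on [-V_max, V_max]; EPSO speeds uniform on the (strictly
    positive) ``speed_init_range``. Every personal best starts at the
    initial position with unknown (-inf) fitness.
    """
    if n < 1:
        raise ValueError("need at least one gene")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    m = config.num_particles
    positions = (rng.random((m, n)) < config.init_bit_prob).astype(np.uint8)
    swarm = Swarm(
        variant=variant,
        positions=positions,
        pbest_positions=positions.copy(),
        pbest_fitness=np.full(m, -np.inf),
        pbest_accuracy=np.zeros(m),
    )
    v_max = config.v_max(n)
    if variant == "bpso":
        swarm.velocities = rng.uniform(-v_max, v_max, size=(m, n))
    else:
        lo, hi = config.speed_init_range
        # hi - U[0,1) * (hi - lo) lies in (lo, hi]: strictly positive speeds
        swarm.speeds = hi - rng.random(m) * (hi - lo)
    return swarm


def update_bests(swarm: Swarm, index: int, fitness: float, accuracy: float) -> bool:
    """Replace particle ``index``'s personal best iff strictly improved.

    Ties keep the incumbent (the fitness already penalizes subset size,
    so no secondary tie-break is applied). Returns True on replacement.
    """
    if fitness > swarm.pbest_fitness[index]:
        swarm.pbest_fitness[index] = fitness
        swarm.pbest_accuracy[index] = accuracy
        swarm.pbest_positions[index] = swarm.positions[index]
        return True
    return False


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    inertia: float
    gbest_fitness: float
    gbest_accuracy: float
    gbest_num_genes: int


@dataclass
class RunResult:
    """Outcome of one optimizer run: the global best and its trajectory."""

    variant: str
    config: SwarmConfig
    gbest_position: np.ndarray
    gbest_fitness: float
    gbest_accuracy: float
    gbest_num_genes: int
    trajectory: list = field(default_factory=list)
    wall_time: float = 0.0

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": r.iteration,
                    "w": r.inertia,
                    "gbest_fitness": r.gbest_fitness,
                    "gbest_accuracy": r.gbest_accuracy,
                    "gbest_num_genes": r.gbest_num_genes,
                }
                for r in self.trajectory
            ]
        )

    def write_trajectory(self, path, sep="\t") -> None:
        self.trajectory_frame().to_csv(path, sep=sep, index=False)


def run_optimizer(dataset: ExpressionDataset, config: SwarmConfig,
                  variant: str, evaluator: FitnessEvaluator = None,
                  standardize: bool = False) -> RunResult:
    """Run one full swarm optimization over the dataset's genes.

    Returns the best position ever evaluated (by fitness), its LOOCV
    accuracy and gene count, and a per-iteration log of the global best.
    Deterministic given (seed, config, dataset).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if dataset.n_samples < 2 or dataset.n_genes < 1:
        raise ValueError("dataset must have >= 2 samples and >= 1 gene")
    t0 = time.perf_counter()
    n = dataset.n_genes
    if evaluator is None:
        evaluator = FitnessEvaluator(dataset, w1=config.w1, w2=config.w2,
                                     standardize=standardize)
    rng = random_stream(config.seed)
    swarm = initialize_swarm(n, config, rng, variant)
    v_max = config.v_max(n)
    w = config.w_init
    gbest_fitness = -np.inf
    gbest_accuracy = 0.0
    gbest_position = swarm.positions[0].copy()
    trajectory = []

    for t in range(config.max_iter):
        for i in range(swarm.num_particles):
            res = evaluator(swarm.positions[i])
            improved = update_bests(swarm, i, res.fitness, res.accuracy)
            if improved and swarm.pbest_fitness[i] > gbest_fitness:
                gbest_fitness = float(swarm.pbest_fitness[i])
                gbest_accuracy = float(swarm.pbest_accuracy[i])
                gbest_position = swarm.pbest_positions[i].copy()
        trajectory.append(
            IterationRecord(
                iteration=t,
                inertia=w,
                gbest_fitness=gbest_fitness,
                gbest_accuracy=gbest_accuracy,
                gbest_num_genes=int(gbest_position.sum()),
            )
        )
        w = update_inertia(w, t, config)
        for i in range(swarm.num_particles):
            if variant == "bpso":
                r1 = rng.random(n)
                r2 = rng.random(n)
                swarm.velocities[i] = bpso_velocity_step(
                    swarm.velocities[i], swarm.positions[i],
                    swarm.pbest_positions[i], gbest_position,
                    w, config.c1, config.c2, v_max, r1, r2,
                )
                swarm.positions[i] = bpso_position_step(
                    swarm.velocities[i], rng.random(n)
                )
            else:
                r1 = rng.random()
                r2 = rng.random()
                swarm.speeds[i] = epso_speed_step(
                    swarm.speeds[i], swarm.positions[i],
                    swarm.pbest_positions[i], gbest_position,
                    w, config.c1, config.c2, v_max, r1, r2,
                )
                swarm.positions[i] = epso_position_step(
                    swarm.speeds[i], rng.random(n), config.sigmoid_steepness,
                    config.min_set_prob,
                )

    return RunResult(
        variant=variant,
        config=config,
        gbest_position=gbest_position,
        gbest_fitness=gbest_fitness,
        gbest_accuracy=gbest_accuracy,
        gbest_num_genes=int(gbest_position.sum()),
        trajectory=trajectory,
        wall_time=time.perf_counter() - t0,
    )
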