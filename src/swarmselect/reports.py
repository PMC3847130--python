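"""Repeated-run aggregation: best / average / standard deviation of
accuracy, selected-gene count and runtime over independent runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SwarmConfig
from .dataset import ExpressionDataset
from .swarm import run_optimizer


@dataclass
class AggregateReport:
    """Per-run rows plus summary statistics over repeated runs.

    ``per_run`` columns: run, seed, accuracy, n_genes, fitness, time_s.
    Best means highest accuracy / fewest genes / lowest time; the SD is
    the sample standard deviation (ddof=1; 0 for a single run).
    """

    variant: str
    per_run: pd.DataFrame

    def summary(self) -> dict:
        out = {}
        for col, best in (("accuracy", "max"), ("n_genes", "min"), ("time_s", "min")):
            x = self.per_run[col].to_numpy(dtype=float)
            out[col] = {
                "best": float(getattr(np, best)(x)),
                "average": float(x.mean()),
                "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
            }
        return out

    def format_summary(self) -> str:
        s = self.summary()
        lines = [f"variant: {self.variant}  (n_runs={len(self.per_run)})"]
        labels = {
            "accuracy": ("Accuracy (%)", 100.0),
            "n_genes": ("#Selected genes", 1.0),
            "time_s": ("Time (s)", 1.0),
        }
        for col, (label, scale) in labels.items():
            v = s[col]
            lines.append(
                f"{label}: best {v['best'] * scale:.2f}, "
                f"Average ± S.D. {v['average'] * scale:.2f} "
                f"± {v['sd'] * scale:.2f}"
            )
        return "\n".join(lines)

    def write(self, path, sep="\t") -> None:
        self.per_run.to_csv(path, sep=sep, index=False)


def run_repeated(dataset: ExpressionDataset, config: SwarmConfig,
                 variant: str, n_runs: int = 10) -> AggregateReport:
    """Run the optimizer ``n_runs`` times with per-run seeds derived as
    master seed + run index, and aggregate the three criteria
    (accuracy, gene count, runtime). Fully reproducible from the master
    seed, and each recorded per-run seed re-runs that run alone.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rows = []
    for run in range(n_runs):
        cfg = config.with_(seed=config.seed + run)
        result = run_optimizer(dataset, cfg, variant)
        rows.append({
            "run": run + 1,
            "seed": cfg.seed,
            "accuracy": result.gbest_accuracy,
            "n_genes": result.gbest_num_genes,
            "fitness": result.gbest_fitness,
            "time_s": result.wall_time,
        })
    return AggregateReport(variant=variant, per_run=pd.DataFrame(rows))
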