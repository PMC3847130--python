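"""Synthetic labeled expression matrices with planted informative genes.

The generator emulates the shape of public microarray benchmarks
(thousands of genes, tens to hundreds of samples, 2-11 classes) while
keeping ground truth: background genes are independent zero-mean
Gaussian noise; each planted informative gene receives a class-dependent
mean shift of ``class_index * effect_size * noise_sd``, so class 0 stays
at baseline and higher classes separate progressively. Class sizes are
as balanced as divisibility allows unless explicit proportions are
given. Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``effect_size`` is the per-class mean shift in units of the noise SD;
    0 makes planted genes indistinguishable from background.
    ``class_proportions`` (optional) gives relative class sizes; the
    default is balanced classes.
    """

    n_samples: int = 30
    n_genes: int = 100
    n_classes: int = 3
    n_informative: int = 5
    effect_size: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0
    class_proportions: tuple = None

    def __post_init__(self):
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_samples < 2 * self.n_classes:
            raise ValueError("need at least two samples per class")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.class_proportions is not None:
            if len(self.class_proportions) != self.n_classes:
                raise ValueError("one proportion per class required")
            if min(self.class_proportions) <= 0:
                raise ValueError("class proportions must be positive")


@dataclass
class SyntheticDataset:
    """An ExpressionDataset plus the identities of the planted genes."""

    dataset: ExpressionDataset
    informative_genes: np.ndarray      # gene ids of the planted genes
    informative_indices: np.ndarray    # their column indices
    spec: SyntheticSpec = field(default=None)

    @property
    def informative_mask(self) -> np.ndarray:
        mask = np.zeros(self.dataset.n_genes, dtype=bool)
        mask[self.informative_indices] = True
        return mask


def _class_sizes(spec: SyntheticSpec) -> np.ndarray:
    if spec.class_proportions is None:
        base = np.full(spec.n_classes, spec.n_samples // spec.n_classes)
        base[: spec.n_samples % spec.n_classes] += 1
        return base
    p = np.asarray(spec.class_proportions, dtype=float)
    p = p / p.sum()
    sizes = np.floor(p * spec.n_samples).astype(int)
    sizes = np.maximum(sizes, 1)
    # distribute the remainder to the largest fractional parts
    while sizes.sum() < spec.n_samples:
        sizes[np.argmax(p * spec.n_samples - sizes)] += 1
    while sizes.sum() > spec.n_samples:
        sizes[np.argmax(sizes)] -= 1
    return sizes


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one synthetic dataset according to ``spec``."""
    rng = np.random.default_rng(spec.seed)
    sizes = _class_sizes(spec)
    labels = np.repeat(np.arange(spec.n_classes), sizes)
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_genes))
    informative = np.sort(
        rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    )
    shift = labels[:, None] * spec.effect_size * spec.noise_sd
    values[:, informative] += shift
    width = len(str(spec.n_genes))
    gene_ids = np.array([f"g{j:0{width}d}" for j in range(spec.n_genes)], dtype=object)
    sample_ids = np.array(
        [f"s{i:0{len(str(spec.n_samples))}d}" for i in range(spec.n_samples)],
        dtype=object,
    )
    dataset = ExpressionDataset(
        values=values,
        labels=labels,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        label_names=np.array([f"class_{c}" for c in range(spec.n_classes)],
                             dtype=object),
    )
    return SyntheticDataset(
        dataset=dataset,
        informative_genes=gene_ids[informative],
        informative_indices=informative,
        spec=spec,
    )


def make_expression(n_samples=30, n_genes=100, n_classes=3, n_informative=5,
                    effect_size=5.0, noise_sd=1.0, seed=0,
                    class_proportions=None) -> SyntheticDataset:
    """Convenience wrapper around :func:`generate_dataset`."""
    return generate_dataset(SyntheticSpec(
        n_samples=n_samples, n_genes=n_genes, n_classes=n_classes,
        n_informative=n_informative, effect_size=effect_size,
        noise_sd=noise_sd, seed=seed, class_proportions=class_proportions,
    ))
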