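"""Wrapper fitness: LOOCV accuracy of an SVM on the selected genes,
combined with a subset-size reward.

    fitness(X_i) = w1 * A(X_i) + w2 * (n - R(X_i)) / n

where A is leave-one-out cross-validated classification accuracy on the
columns selected by the particle, R the number of selected genes and n
the total gene count. An empty subset receives fitness 0 (evaluating
the formula literally at R = 0 would reward selecting nothing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .dataset import ExpressionDataset


@dataclass(frozen=True)
class ClassifierSpec:
    """The shipped classifier: RBF-kernel SVM, one-against-one multiclass.

    ``C`` is the soft-margin cost (default 1); gamma follows the 1/k rule
    with k = number of genes fed to the classifier, so the kernel width
    tracks the subset dimensionality.
    """

    C: float = 1.0
    kernel: str = "rbf"

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")

    def build(self, n_selected: int):
        if n_selected < 1:
            raise ValueError("gamma = 1/k requires at least one selected gene")
        return SVC(
            kernel=self.kernel,
            C=self.C,
            gamma=1.0 / n_selected,
            decision_function_shape="ovo",
        )


@dataclass(frozen=True)
class FitnessResult:
    accuracy: float
    n_selected: int
    fitness: float


def subset_columns(dataset: ExpressionDataset, position) -> ExpressionDataset:
    """Keep exactly the genes whose bits are 1, order preserved."""
    bits = np.asarray(position)
    if bits.shape != (dataset.n_genes,):
        raise ValueError("position length must equal the gene count")
    return dataset.subset_genes(bits.astype(bool))


def loocv_accuracy(dataset: ExpressionDataset, position=None, spec=None,
                   classifier_factory=None) -> float:
    """Leave-one-out cross-validated accuracy on the selected genes.

    Each of the N folds trains on the other N-1 samples (restricted to
    the selected genes) and predicts the held-out sample; the result is
    the fraction of correct predictions. Deterministic given its inputs.
    A training fold containing a single class yields a constant
    prediction of that class.

    Parameters
    ----------
    dataset : ExpressionDataset
    position : optional bit vector; if given the dataset is first
        restricted to the set bits. All genes are used when omitted.
    spec : ClassifierSpec, default RBF SVM with C = 1, gamma = 1/k.
    classifier_factory : optional callable ``k -> estimator`` overriding
        ``spec``; any object with fit(X, y)/predict(X) works.
    """
    if position is not None:
        dataset = subset_columns(dataset, position)
    if dataset.n_genes < 1:
        raise ValueError("LOOCV needs at least one selected gene")
    if dataset.n_samples < 2:
        raise ValueError("LOOCV needs at least two samples")
    if classifier_factory is None:
        spec = spec or ClassifierSpec()
        classifier_factory = spec.build
    X, y = dataset.values, dataset.labels
    n = dataset.n_samples
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        classes = np.unique(y_train)
        if classes.size == 1:
            pred = classes[0]
        else:
            clf = classifier_factory(dataset.n_genes)
            clf.fit(X[mask], y_train)
            pred = clf.predict(X[i : i + 1])[0]
        correct += int(pred == y[i])
    return correct / n


def fitness_value(accuracy: float, n_selected: int, n_total: int,
                  w1: float = 0.8, w2: float = 0.2,
                  empty_fitness: float = 0.0) -> float:
    """Combine accuracy and subset size into the scalar fitness.

    Returns ``w1 * accuracy + w2 * (n_total - n_selected) / n_total`` for
    a non-empty subset and ``empty_fitness`` (default 0) otherwise.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if n_selected > n_total:
        raise ValueError("selected gene count exceeds the gene total")
    if n_selected < 0:
        raise ValueError("negative gene count")
    if abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if n_selected == 0:
        return empty_fitness
    return w1 * accuracy + w2 * (n_total - n_selected) / n_total


class FitnessEvaluator:
    """Evaluate (and memoize) particle positions against a dataset.

    Positions recur heavily once a swarm starts converging, so results
    are cached by the exact bit pattern. The cache never affects the
    optimizer's random stream.
    """

    def __init__(self, dataset: ExpressionDataset, w1=0.8, w2=0.2,
                 spec=None, classifier_factory=None, standardize=False,
                 empty_fitness=0.0):
        self.dataset = dataset.standardized() if standardize else dataset
        self.w1, self.w2 = w1, w2
        self.spec = spec or ClassifierSpec()
        self.classifier_factory = classifier_factory
        self.empty_fitness = empty_fitness
        self.n_evaluations = 0  # excludes cache hits
        self._cache: dict = {}

    def __call__(self, position) -> FitnessResult:
        bits = np.ascontiguousarray(np.asarray(position, dtype=np.uint8))
        key = bits.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        n_selected = int(bits.sum())
        if n_selected == 0:
            result = FitnessResult(0.0, 0, self.empty_fitness)
        else:
            acc = loocv_accuracy(
                self.dataset, bits, spec=self.spec,
                classifier_factory=self.classifier_factory,
            )
            result = FitnessResult(
                acc, n_selected,
                fitness_value(acc, n_selected, self.dataset.n_genes,
                              self.w1, self.w2, self.empty_fitness),
            )
            self.n_evaluations += 1
        self._cache[key] = result
        return result
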