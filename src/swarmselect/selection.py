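"""Scikit-learn estimator surface for swarm-based gene selection."""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_random_state, validate_data

from .config import DEFAULT_MIN_SET_PROB, SwarmConfig
from .dataset import ExpressionDataset
from .fitness import FitnessEvaluator
from .swarm import run_optimizer


class PSOGeneSelector(SelectorMixin, BaseEstimator):
    """Wrapper feature selection by binary particle swarm optimization.

    Each particle is a bit mask over features; its fitness is
    ``w1 * accuracy + w2 * (n - R)/n`` where accuracy is the leave-one-out
    cross-validated score of an RBF SVM (C = 1, gamma = 1/R,
    one-against-one) on the R selected features. Two update rules are
    available:

    - ``variant="bpso"``: the conventional binary PSO with per-dimension
      velocities and the standard sigmoid transfer function; over many
      dimensions it tends to keep about half of all features selected.
    - ``variant="epso"`` (default): the enhanced rule with one
      non-negative scalar speed per particle, a steepened sigmoid and an
      inverted bit rule, which bounds P(bit = 1) by 0.5 and drives the
      swarm toward small feature subsets.

    Parameters mirror :class:`~swarmselect.config.SwarmConfig`;
    ``random_state`` follows the scikit-learn convention.

    Attributes
    ----------
    support_ : bool ndarray of shape (n_features,)
        Mask of the selected features (the best position found).
    gbest_fitness_, gbest_accuracy_ : float
        Fitness and LOOCV accuracy of the best position.
    n_selected_ : int
        Number of selected features.
    trajectory_ : pandas.DataFrame
        Per-iteration global-best log (iteration, w, fitness, accuracy,
        gene count).
    run_result_ : RunResult
        The full engine output.

    Examples
    --------
    >>> from swarmselect import make_expression, PSOGeneSelector
    >>> syn = make_expression(n_samples=20, n_genes=40, n_classes=2,
    ...                       n_informative=3, effect_size=8, seed=0)
    >>> sel = PSOGeneSelector(num_particles=10, max_iter=10, random_state=0)
    >>> X_small = sel.fit_transform(syn.dataset.values, syn.dataset.labels)
    >>> X_small.shape[1] == sel.n_selected_
    True
    """

    def __init__(self, variant="epso", num_particles=100, max_iter=500,
                 c1=2.0, c2=2.0, w_init=1.4, w_floor=0.4,
                 v_max_fraction=1.0 / 3.0, w1=0.8, w2=0.2,
                 sigmoid_steepness=5.0, init_bit_prob=0.5,
                 speed_init_range=(0.0, 1.0),
                 min_set_prob=DEFAULT_MIN_SET_PROB, standardize=False,
                 classifier_factory=None, random_state=None):
        self.variant = variant
        self.num_particles = num_particles
        self.max_iter = max_iter
        self.c1 = c1
        self.c2 = c2
        self.w_init = w_init
        self.w_floor = w_floor
        self.v_max_fraction = v_max_fraction
        self.w1 = w1
        self.w2 = w2
        self.sigmoid_steepness = sigmoid_steepness
        self.init_bit_prob = init_bit_prob
        self.speed_init_range = speed_init_range
        self.min_set_prob = min_set_prob
        self.standardize = standardize
        self.classifier_factory = classifier_factory
        self.random_state = random_state

    def _seed(self) -> int:
        if isinstance(self.random_state, numbers.Integral):
            return int(self.random_state)
        return int(check_random_state(self.random_state).randint(2**31))

    def _config(self) -> SwarmConfig:
        return SwarmConfig(
            num_particles=self.num_particles, max_iter=self.max_iter,
            c1=self.c1, c2=self.c2, w_init=self.w_init, w_floor=self.w_floor,
            v_max_fraction=self.v_max_fraction, w1=self.w1, w2=self.w2,
            sigmoid_steepness=self.sigmoid_steepness,
            init_bit_prob=self.init_bit_prob,
            speed_init_range=tuple(self.speed_init_range),
            min_set_prob=self.min_set_prob,
            seed=self._seed(),
        )

    def fit(self, X, y):
        """Search for the best feature subset on (X, y)."""
        X, y = validate_data(self, X, y, dtype=np.float64)
        classes, codes = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("y must contain at least two classes")
        self.classes_ = classes
        dataset = ExpressionDataset(
            values=X,
            labels=codes,
            gene_ids=np.array([f"f{j}" for j in range(X.shape[1])], dtype=object),
            sample_ids=np.array([f"s{i}" for i in range(X.shape[0])], dtype=object),
        )
        config = self._config()
        evaluator = FitnessEvaluator(
            dataset, w1=config.w1, w2=config.w2,
            classifier_factory=self.classifier_factory,
            standardize=self.standardize,
        )
        result = run_optimizer(dataset, config, self.variant, evaluator=evaluator)
        self.run_result_ = result
        self.support_ = result.gbest_position.astype(bool)
        self.gbest_fitness_ = result.gbest_fitness
        self.gbest_accuracy_ = result.gbest_accuracy
        self.n_selected_ = result.gbest_num_genes
        self.trajectory_ = result.trajectory_frame()
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
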