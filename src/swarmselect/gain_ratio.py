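"""Entropy-based gain-ratio ranking of genes, used to pre-select the
top-k genes (k = 500 in the benchmark protocol) before swarm search.

Each gene is scored by its single best binary split: candidate
thresholds are midpoints between consecutive distinct sorted expression
values; the threshold maximizing the information gain of the induced
two-way partition is kept, and the score is that gain normalized by the
partition's own entropy (the split information). Constant genes, and
genes whose best split carries no information, score 0. Because only
the ordering of values matters, the ranking is invariant to monotone
transformations of a gene's expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .dataset import ExpressionDataset


def class_entropy(labels) -> float:
    """Shannon entropy of the class distribution, in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("need at least one label")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def best_split_gain(values, labels):
    """Best binary split of one gene's expression against the labels.

    Returns ``(threshold, info_gain, split_info)`` for the threshold
    maximizing information gain; ties keep the lowest threshold. A
    constant gene returns ``(None, 0.0, 0.0)``.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must be aligned")
    n = values.size
    order = np.argsort(values, kind="stable")
    v_sorted = values[order]
    y_sorted = labels[order]

    # candidate split points: between consecutive distinct values
    boundaries = np.flatnonzero(np.diff(v_sorted) > 0) + 1  # left-side sizes
    if boundaries.size == 0:
        return None, 0.0, 0.0

    classes, y_codes = np.unique(y_sorted, return_inverse=True)
    onehot = np.zeros((n, classes.size))
    onehot[np.arange(n), y_codes] = 1.0
    cum = np.cumsum(onehot, axis=0)  # cum[i-1] = class counts of first i rows

    h_total = class_entropy(labels)
    nl = boundaries.astype(np.float64)
    nr = n - nl
    left_counts = cum[boundaries - 1]            # (n_splits, K)
    right_counts = cum[-1] - left_counts

    def _entropy(counts, sizes):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / sizes[:, None]
            terms = np.where(p > 0, p * np.log2(p), 0.0)
        return -terms.sum(axis=1)

    h_children = (nl / n) * _entropy(left_counts, nl) + (nr / n) * _entropy(
        right_counts, nr
    )
    gains = h_total - h_children
    best = int(np.argmax(gains))  # argmax keeps the first (lowest) threshold
    gain = float(max(gains[best], 0.0))
    pl, pr = nl[best] / n, nr[best] / n
    split_info = float(-(pl * np.log2(pl) + pr * np.log2(pr)))
    threshold = float((v_sorted[boundaries[best] - 1] + v_sorted[boundaries[best]]) / 2)
    return threshold, gain, split_info


def gain_ratio(values, labels) -> float:
    """Gain ratio of a gene: best-split info gain / split information.

    Returns 0 when the gene is constant, the gain is 0, or the split
    information is 0 (degenerate one-sided split).
    """
    _, gain, split_info = best_split_gain(values, labels)
    if gain <= 0.0 or split_info <= 0.0:
        return 0.0
    return gain / split_info


@dataclass(frozen=True)
class RankedGene:
    gene_id: str
    score: float
    threshold: float  # None for constant genes


def rank_genes(dataset: ExpressionDataset) -> pd.DataFrame:
    """Score every gene; returns a frame sorted by score (stable ties).

    Columns: gene, score, threshold, rank (1-based). Ties are broken by
    original gene order for reproducibility.
    """
    rows = []
    for j in range(dataset.n_genes):
        thr, gain, split_info = best_split_gain(dataset.values[:, j], dataset.labels)
        score = gain / split_info if (gain > 0 and split_info > 0) else 0.0
        rows.append((dataset.gene_ids[j], score, thr))
    frame = pd.DataFrame(rows, columns=["gene", "score", "threshold"])
    order = np.argsort(-frame["score"].to_numpy(), kind="stable")
    frame = frame.iloc[order].reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


def select_top_k(dataset: ExpressionDataset, k: int = 500):
    """Keep the min(k, n) highest-scoring genes (original column order).

    Returns ``(reduced_dataset, ranking_frame)``. Downstream fitness uses
    the reduced gene count as its n.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranking = rank_genes(dataset)
    keep_ids = set(ranking["gene"].iloc[: min(k, dataset.n_genes)])
    mask = np.array([g in keep_ids for g in dataset.gene_ids])
    return dataset.subset_genes(mask), ranking


class GainRatioSelector(SelectorMixin, BaseEstimator):
    """Select the k genes with the highest gain-ratio score.

    A filter-style transformer analogous to ``SelectKBest``, scoring each
    feature by its best single binary split's gain ratio.

    Parameters
    ----------
    k : int, default 500
        Number of features to keep (capped at the feature count).

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
    thresholds_ : ndarray of shape (n_features,)
        Best split threshold per feature (NaN for constant features).
    """

    def __init__(self, k: int = 500):
        self.k = k

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=np.float64)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        scores = np.empty(X.shape[1])
        thresholds = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            thr, gain, split_info = best_split_gain(X[:, j], y)
            scores[j] = gain / split_info if (gain > 0 and split_info > 0) else 0.0
            thresholds[j] = np.nan if thr is None else thr
        self.scores_ = scores
        self.thresholds_ = thresholds
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        k = min(self.k, self.scores_.size)
        top = np.argsort(-self.scores_, kind="stable")[:k]
        mask = np.zeros(self.scores_.size, dtype=bool)
        mask[top] = True
        return mask
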