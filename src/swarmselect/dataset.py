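"""Labeled expression-matrix container shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExpressionDataset:
    """A labeled samples x genes expression matrix.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Real-valued expression levels. Must be finite (no NaN/inf).
    labels : ndarray of shape (n_samples,)
        Integer class codes ``0..K-1``.
    gene_ids : ndarray of str, shape (n_genes,)
        Unique gene identifiers, column order.
    sample_ids : ndarray of str, shape (n_samples,)
        Sample identifiers, row order.
    label_names : ndarray, optional
        Original categorical label for each code, so files round-trip.
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    label_names: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n, g = self.values.shape
        if self.labels.shape != (n,):
            raise ValueError(f"labels length {self.labels.shape} != n_samples {n}")
        if self.gene_ids.shape != (g,):
            raise ValueError(f"gene_ids length {len(self.gene_ids)} != n_genes {g}")
        if self.sample_ids.shape != (n,):
            raise ValueError("sample_ids length inconsistent with matrix rows")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at sample "
                f"{self.sample_ids[bad[0]]!r}, gene {self.gene_ids[bad[1]]!r}"
            )
        if self.label_names is None:
            self.label_names = np.unique(self.labels)
        self.label_names = np.asarray(self.label_names, dtype=object)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    def subset_genes(self, index) -> "ExpressionDataset":
        """Return a copy restricted to the given gene columns.

        ``index`` may be a boolean mask of length n_genes or integer
        column indices; column order is preserved as given.
        """
        index = np.asarray(index)
        if index.dtype == bool:
            if index.shape != (self.n_genes,):
                raise ValueError("boolean gene mask has wrong length")
            cols = np.flatnonzero(index)
        else:
            cols = index.astype(np.intp)
        return ExpressionDataset(
            values=self.values[:, cols],
            labels=self.labels.copy(),
            gene_ids=self.gene_ids[cols],
            sample_ids=self.sample_ids.copy(),
            label_names=self.label_names.copy(),
        )

    def standardized(self) -> "ExpressionDataset":
        """Per-gene z-scoring (mean 0, SD 1; constant genes left at 0)."""
        mu = self.values.mean(axis=0)
        sd = self.values.std(axis=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        return ExpressionDataset(
            values=(self.values - mu) / sd,
            labels=self.labels.copy(),
            gene_ids=self.gene_ids.copy(),
            sample_ids=self.sample_ids.copy(),
            label_names=self.label_names.copy(),
        )
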