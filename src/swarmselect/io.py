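"""Reading and writing the delimited expression-matrix format.

Canonical layout: one row per sample, first column the sample id, one
designated label column, remaining columns gene expression values with
gene ids in the header. A transposed (genes-as-rows) orientation is
accepted behind a flag: first column gene ids, one column per sample,
and one extra row (named like the label column) holding the labels.
TSV by default; comma also accepted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset


class LoadError(ValueError):
    """Raised when an expression file violates the format contract."""


def _encode_labels(raw):
    names, codes = np.unique(np.asarray(raw, dtype=object), return_inverse=True)
    if len(names) < 2:
        raise LoadError("dataset must contain at least two classes")
    return codes.astype(np.int64), names


def read_expression_matrix(path, label_col="label", sep="\t",
                           genes_as_rows=False) -> ExpressionDataset:
    """Load a labeled expression matrix, validating every cell.

    Raises :class:`LoadError` naming the offending row/column on missing
    or non-numeric cells, a missing label column, or duplicate gene ids.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if not genes_as_rows and len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1} - {label_col})
        raise LoadError(f"duplicate gene id(s): {dupes}")
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=object)
    if genes_as_rows:
        if label_col not in frame.index:
            raise LoadError(f"label row {label_col!r} not found")
        frame = frame.T
    if label_col not in frame.columns:
        raise LoadError(f"label column {label_col!r} not found")
    labels_raw = frame[label_col]
    if labels_raw.isna().any():
        sample = frame.index[labels_raw.isna()][0]
        raise LoadError(f"missing label for sample {sample!r}")
    expr = frame.drop(columns=[label_col])
    gene_ids = expr.columns.to_numpy(dtype=object)
    if len(set(gene_ids)) != len(gene_ids):
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise LoadError(f"duplicate gene id(s): {dupes}")
    values = expr.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise LoadError(
            f"missing or non-numeric expression value at sample "
            f"{expr.index[i]!r}, gene {gene_ids[j]!r}"
        )
    codes, names = _encode_labels(labels_raw.to_numpy())
    return ExpressionDataset(
        values=values,
        labels=codes,
        gene_ids=gene_ids,
        sample_ids=expr.index.to_numpy(dtype=object),
        label_names=names,
    )


def write_expression_matrix(dataset: ExpressionDataset, path,
                            label_col="label", sep="\t") -> None:
    """Write the canonical samples-as-rows layout."""
    frame = pd.DataFrame(dataset.values, index=pd.Index(dataset.sample_ids, name="sample"),
                         columns=dataset.gene_ids)
    frame.insert(0, label_col, dataset.label_names[dataset.labels])
    frame.to_csv(path, sep=sep)


def write_truth(synthetic, path) -> None:
    """Write the planted informative gene ids of a synthetic dataset."""
    pd.DataFrame({"gene": synthetic.informative_genes}).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["gene"].to_numpy(dtype=object)
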