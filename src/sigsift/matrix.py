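"""Expression-matrix and label-table containers and their TSV dialect.

An expression matrix is a :class:`pandas.DataFrame` with gene identifiers as
the row index and sample identifiers as columns; every cell is a finite
float.  A label vector is a :class:`pandas.Series` of class labels indexed by
sample identifier.  These two objects are the substrate of every pipeline
stage, so validation lives here and every stage calls it at its boundary.

On disk a matrix is tab-separated with the gene ID in the first column and a
header row of sample IDs; labels are a two-column TSV (sample_id, class).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "validate_matrix",
    "validate_labels",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
]


def validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check matrix invariants: unique gene/sample IDs, all-finite floats.

    Returns the matrix coerced to float64.  Raises ``ValueError`` naming the
    violated invariant otherwise.
    """
    if not isinstance(m, pd.DataFrame):
        raise TypeError("expression matrix must be a pandas DataFrame")
    if m.index.has_duplicates:
        dupes = m.index[m.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene identifiers: {dupes}")
    if m.columns.has_duplicates:
        dupes = m.columns[m.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate sample identifiers: {dupes}")
    try:
        values = m.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"matrix contains non-numeric values: {exc}") from exc
    if not np.isfinite(values).all():
        n_bad = int((~np.isfinite(values)).sum())
        raise ValueError(f"matrix contains {n_bad} non-finite cells")
    return m.astype(np.float64)


def validate_labels(labels: pd.Series, matrix: pd.DataFrame | None = None) -> pd.Series:
    """Check a label vector; optionally check it covers a matrix's samples."""
    if not isinstance(labels, pd.Series):
        raise TypeError("labels must be a pandas Series indexed by sample ID")
    if labels.index.has_duplicates:
        raise ValueError("duplicate sample identifiers in labels")
    if labels.isna().any():
        raise ValueError("labels contain missing values")
    if matrix is not None:
        missing = [s for s in matrix.columns if s not in labels.index]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        labels = labels.loc[list(matrix.columns)]
    return labels.astype(str)


def read_matrix(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    return validate_matrix(m)


def write_matrix(m: pd.DataFrame, path) -> None:
    validate_matrix(m).rename_axis("gene_id").to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    return validate_labels(s)


def write_labels(labels: pd.Series, path) -> None:
    validate_labels(labels).rename("class").rename_axis("sample_id").to_csv(path, sep="\t")
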