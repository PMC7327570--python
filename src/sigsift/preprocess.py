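"""Cross-platform merging and quantile normalization.

When samples come from two array platforms, only the genes measured on both
are comparable, and even then each sample carries its own intensity
distribution.  :func:`intersect_genes` restricts two matrices to their shared
genes and concatenates the samples; :func:`quantile_normalize` then forces
every sample onto a common reference distribution (the row means of the
column-sorted matrix), the standard remedy that makes additive batch offsets
vanish at the distribution level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import validate_matrix

__all__ = ["intersect_genes", "quantile_normalize"]


def intersect_genes(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Merge two matrices on their common genes.

    Rows of the result are the genes present in both inputs, sorted
    lexicographically; columns are ``a``'s samples followed by ``b``'s.
    Raises if the inputs share sample IDs or share no genes.
    """
    a = validate_matrix(a)
    b = validate_matrix(b)
    overlap_samples = a.columns.intersection(b.columns)
    if len(overlap_samples) > 0:
        raise ValueError(
            f"sample identifiers appear in both matrices: {overlap_samples.tolist()[:5]}"
        )
    common = sorted(a.index.intersection(b.index))
    if not common:
        raise ValueError("the two matrices share no gene identifiers; nothing to merge")
    return pd.concat([a.loc[common], b.loc[common]], axis=1)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples (columns) to a shared reference distribution.

    The reference is the vector of row means of the column-sorted matrix.
    Each value is replaced by the reference value at its within-column rank;
    tied values within a column receive the mean of the reference values at
    their tied positions, matching the behaviour of the classic
    ``normalize.quantiles`` routine.  Column dimensions, and the rank order
    within each column, are preserved.
    """
    m = validate_matrix(m)
    if m.shape[1] < 1:
        raise ValueError("matrix must have at least one sample")
    values = m.to_numpy()
    reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the reference over runs of tied values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(col)]])
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[order[s:e]] = reference[s:e].mean()
        out[:, j] = assigned
    return pd.DataFrame(out, index=m.index, columns=m.columns)
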