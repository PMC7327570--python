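"""Simulate a two-platform cohort and remove the batch offset by quantile normalization.

Builds a 4-class expression matrix with a +2 offset on half the samples
(emulating a second array platform), then shows that after quantile
normalization the between-batch mean gap is gone while the class signal in
the planted genes is preserved.
"""

import numpy as np

from sigsift import SyntheticConfig, generate_dataset, quantile_normalize

cfg = SyntheticConfig(
    class_sizes=(20, 20, 20, 20),
    n_genes=300,
    n_informative=8,
    effect_size=3.0,
    batch_fraction=0.5,
    batch_shift=2.0,
    seed=42,
)
matrix, labels, truth = generate_dataset(cfg)
batch = truth.batch_assignment

def batch_gap(m):
    return float(
        m.loc[:, batch == 1].to_numpy().mean() - m.loc[:, batch == 0].to_numpy().mean()
    )

normalized = quantile_normalize(matrix)
g = truth.informative_genes[0]
elevated = truth.per_gene_class_means.loc[g].idxmax()
signal = (
    normalized.loc[g, labels[labels == elevated].index].mean()
    - normalized.loc[g, labels[labels != elevated].index].mean()
)

print(f"samples: {matrix.shape[1]}, genes: {matrix.shape[0]}, planted: {len(truth.informative_genes)}")
print(f"between-batch mean gap before normalization: {batch_gap(matrix):+.3f}")
print(f"between-batch mean gap after  normalization: {batch_gap(normalized):+.3f}")
print(f"class-mean separation of planted gene {g} after normalization: {signal:+.3f}")
print("-> the platform offset (2.0) vanishes; the ~3-SD class effect survives")
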