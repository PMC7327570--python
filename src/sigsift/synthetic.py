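"""Synthetic multi-class expression data with planted signature genes.

Real blood-transcriptome cohorts for this kind of signature discovery mix a
handful of truly class-discriminating genes into tens of thousands of
irrelevant ones, collected on more than one array platform and therefore
carrying batch structure.  This module emulates exactly that: a K-class
design with unequal group sizes (defaults mirror a 75/122/71/311 bacterial /
viral / healthy / Kawasaki cohort), i.i.d. Gaussian measurement noise around
gene-specific baselines, a chosen number of planted informative genes whose
mean is shifted in one designated class, and an optional additive per-sample
"platform" offset.

The generator is the test harness for every downstream stage, so it is
deterministic: one root seed is split into independent streams (baselines,
noise, batch assignment) so each aspect can be reproduced in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import validate_matrix

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset", "apply_batch_effect"]

#: default per-class sample counts: bacterial, viral, healthy, Kawasaki
DEFAULT_CLASS_SIZES = (75, 122, 71, 311)
DEFAULT_CLASS_NAMES = ("DB", "DV", "HC", "KD")

# gene-specific baseline expression ~ N(8, 2): log2-intensity-like scale
_BASELINE_MEAN = 8.0
_BASELINE_SD = 2.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    ``effect_size`` is the between-class mean shift of a planted gene in
    units of ``noise_sd``; ``batch_fraction`` of each class's samples are
    assigned to a second platform and receive ``batch_shift`` added to every
    gene.
    """

    class_sizes: tuple[int, ...] = DEFAULT_CLASS_SIZES
    n_genes: int = 2000
    n_informative: int = 20
    effect_size: float = 3.0
    noise_sd: float = 1.0
    batch_fraction: float = 0.0
    batch_shift: float = 0.0
    seed: int = 0
    class_names: tuple[str, ...] | None = None

    def __post_init__(self):
        sizes = tuple(int(c) for c in self.class_sizes)
        object.__setattr__(self, "class_sizes", sizes)
        if len(sizes) < 2:
            raise ValueError("at least 2 classes are required")
        if any(c < 1 for c in sizes):
            raise ValueError("all class_sizes must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("n_informative must satisfy 0 <= n_informative <= n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.batch_fraction <= 1.0:
            raise ValueError("batch_fraction must lie in [0, 1]")
        names = self.class_names
        if names is None:
            if len(sizes) == 4:
                names = DEFAULT_CLASS_NAMES
            else:
                names = tuple(f"C{i + 1}" for i in range(len(sizes)))
        else:
            names = tuple(str(n) for n in names)
            if len(names) != len(sizes):
                raise ValueError("class_names length must match class_sizes")
        object.__setattr__(self, "class_names", names)

    @property
    def n_samples(self) -> int:
        return sum(self.class_sizes)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("class_sizes", "class_names"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: which genes carry signal and their true class means."""

    informative_genes: tuple[str, ...]
    per_gene_class_means: pd.DataFrame = field(repr=False)
    batch_assignment: pd.Series = field(repr=False)


def _stream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[index])


def generate_dataset(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Draw one labeled expression matrix from ``config``.

    Returns ``(matrix, labels, truth)``: a genes x samples DataFrame, a
    per-sample class Series, and the planted ground truth.  Planted gene i
    has its mean raised by ``effect_size * noise_sd`` in one class, cycling
    through the classes so each class owns some discriminating genes.
    Identical configs (including seed) produce bitwise-identical output.
    """
    n_genes, n = config.n_genes, config.n_samples
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids, labels = [], []
    for name, size in zip(config.class_names, config.class_sizes):
        for j in range(size):
            sample_ids.append(f"{name}_{j + 1:03d}")
            labels.append(name)
    labels = pd.Series(labels, index=sample_ids, name="class")

    rng_base = _stream(config.seed, 0)
    rng_noise = _stream(config.seed, 1)
    baselines = rng_base.normal(_BASELINE_MEAN, _BASELINE_SD, size=n_genes)
    values = baselines[:, None] + rng_noise.normal(0.0, config.noise_sd, size=(n_genes, n))

    shift = config.effect_size * config.noise_sd
    informative = gene_ids[: config.n_informative]
    class_of = labels.to_numpy()
    means = pd.DataFrame(
        np.tile(baselines[: config.n_informative, None], (1, len(config.class_names))),
        index=informative,
        columns=list(config.class_names),
    )
    for i, gene in enumerate(informative):
        elevated = config.class_names[i % len(config.class_names)]
        values[i, class_of == elevated] += shift
        means.loc[gene, elevated] += shift

    matrix = pd.DataFrame(values, index=gene_ids, columns=sample_ids)

    # batch assignment crossed with class: a fixed fraction of each class
    # goes to platform 1, so batch never confounds class
    rng_batch = _stream(config.seed, 2)
    batch = pd.Series(0, index=sample_ids, name="batch")
    if config.batch_fraction > 0:
        for name, size in zip(config.class_names, config.class_sizes):
            members = labels.index[labels == name]
            k = int(round(config.batch_fraction * size))
            chosen = rng_batch.choice(members, size=k, replace=False)
            batch.loc[chosen] = 1
        matrix = apply_batch_effect(matrix, batch, config.batch_shift)

    truth = GroundTruth(
        informative_genes=tuple(informative),
        per_gene_class_means=means,
        batch_assignment=batch,
    )
    return matrix, labels, truth


def apply_batch_effect(matrix: pd.DataFrame, batch_assignment, shift: float) -> pd.DataFrame:
    """Add ``shift`` to every gene of the samples flagged 1 in ``batch_assignment``."""
    matrix = validate_matrix(matrix)
    assignment = np.asarray(pd.Series(batch_assignment).to_numpy())
    if assignment.shape[0] != matrix.shape[1]:
        raise ValueError(
            f"batch_assignment has {assignment.shape[0]} entries "
            f"but the matrix has {matrix.shape[1]} samples"
        )
    if not np.isin(assignment, [0, 1]).all():
        raise ValueError("batch_assignment must be a 0/1 vector")
    out = matrix.copy()
    out.loc[:, assignment == 1] += float(shift)
    return out
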