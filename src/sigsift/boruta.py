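"""All-relevant gene filtering with shadow features (the Boruta algorithm).

Most genes in a transcriptome carry no information about the class labels;
Boruta removes them while keeping *every* informative gene, not just a
minimal predictive subset.  Each iteration appends a "shadow" copy of every
gene — its values permuted across samples, destroying any association with
the labels — fits a random forest on real plus shadow features, and scores a
*hit* for each real gene whose impurity-decrease importance exceeds the best
shadow's.  Hits accumulate across iterations; a two-sided binomial test at
level ``alpha`` (Bonferroni-corrected across the genes still in play)
confirms genes hitting significantly more than half the time and rejects
genes hitting significantly less.  Rejected genes leave the forest, genes
still undecided at ``max_iter`` are labelled tentative and excluded from the
confirmed set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .matrix import validate_matrix, validate_labels

__all__ = [
    "BorutaParams",
    "BorutaResult",
    "make_shadow_features",
    "boruta_run",
    "confirmed_features",
]

SHADOW_PREFIX = "shadow__"

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


@dataclass(frozen=True)
class BorutaParams:
    n_estimators: int = 100
    max_iter: int = 100
    alpha: float = 0.05
    bonferroni: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass
class BorutaResult:
    """Per-gene decisions plus the importance trace of the run.

    ``importance_history`` is iterations x genes (NaN once a gene has left
    the forest); ``shadow_max_history`` holds each iteration's best shadow
    importance; ``hits`` the per-gene hit counts over iterations in play.
    """

    status: pd.Series
    importance_history: pd.DataFrame = field(repr=False)
    shadow_max_history: list[float] = field(repr=False)
    hits: pd.Series = field(repr=False)

    @property
    def n_confirmed(self) -> int:
        return int((self.status == CONFIRMED).sum())

    def mean_importance(self) -> pd.Series:
        return self.importance_history.mean(axis=0, skipna=True)


def make_shadow_features(m: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Append one shadow gene per real gene: its values permuted across samples.

    Shadow rows are identified by the ``shadow__`` prefix on the source gene
    ID.  A shadow keeps the exact multiset of its source's values, so any
    importance it earns reflects chance alone.
    """
    m = validate_matrix(m)
    rng = np.random.default_rng(seed)
    shuffled = m.to_numpy().copy()
    for i in range(shuffled.shape[0]):
        rng.shuffle(shuffled[i])
    shadows = pd.DataFrame(
        shuffled, index=[SHADOW_PREFIX + g for g in m.index], columns=m.columns
    )
    return pd.concat([m, shadows], axis=0)


def _binomial_tails(hits: int, n: int) -> tuple[float, float]:
    """One-sided p-values (upper, lower) for hit count under Binomial(n, 1/2)."""
    upper = stats.binom.sf(hits - 1, n, 0.5)
    lower = stats.binom.cdf(hits, n, 0.5)
    return float(upper), float(lower)


def boruta_run(m: pd.DataFrame, labels: pd.Series, params: BorutaParams) -> BorutaResult:
    """Run the iterative shadow-feature filter on a genes x samples matrix."""
    m = validate_matrix(m)
    labels = validate_labels(labels, m)
    class_counts = labels.value_counts()
    if len(class_counts) < 2:
        raise ValueError("labels must contain at least 2 classes")
    if (class_counts < 2).any():
        small = class_counts[class_counts < 2].index.tolist()
        raise ValueError(f"every class needs >= 2 samples; too small: {small}")

    genes = list(m.index)
    y = labels.to_numpy()
    status = pd.Series(TENTATIVE, index=genes, dtype=object)
    hits = pd.Series(0, index=genes, dtype=int)
    iters_in_play = pd.Series(0, index=genes, dtype=int)
    history_rows: list[pd.Series] = []
    shadow_max_history: list[float] = []

    seeds = np.random.SeedSequence(params.seed).generate_state(2 * params.max_iter)
    for it in range(params.max_iter):
        in_play = status.index[status != REJECTED].tolist()
        tentative = status.index[status == TENTATIVE].tolist()
        if not tentative:
            break
        # the shadow pool stays at ALL original genes even after rejection:
        # a shrinking pool would let a chance-correlated survivor beat the
        # max of a handful of fresh shadows nearly every round, inflating
        # the hit count; against max-of-d shadows it wins ~half the time
        # and stays tentative, which is the correct null behaviour
        shadow_rng = np.random.default_rng(int(seeds[2 * it] % (2**31)))
        full = make_shadow_features(m, int(shadow_rng.integers(2**31)))
        shadow_ids = [SHADOW_PREFIX + g for g in genes]
        augmented = full.loc[in_play + shadow_ids]
        forest = RandomForestClassifier(
            n_estimators=params.n_estimators,
            random_state=int(seeds[2 * it + 1] % (2**31)),
            n_jobs=1,
        )
        forest.fit(augmented.to_numpy().T, y)
        importance = pd.Series(forest.feature_importances_, index=augmented.index)
        real_imp = importance.loc[in_play]
        shadow_max = float(importance.loc[importance.index.str.startswith(SHADOW_PREFIX)].max())
        shadow_max_history.append(shadow_max)
        history_rows.append(real_imp.reindex(genes))

        hit_now = real_imp.loc[tentative] > shadow_max
        hits.loc[tentative] += hit_now.astype(int)
        iters_in_play.loc[tentative] += 1

        # Bonferroni over all genes entering the run, held constant across
        # iterations (the all-attribute adjustment of the reference method)
        n_tests = len(genes) if params.bonferroni else 1
        level = params.alpha / 2 / n_tests  # two-sided at alpha, split per tail
        for g in tentative:
            upper, lower = _binomial_tails(int(hits[g]), int(iters_in_play[g]))
            if upper < level:
                status[g] = CONFIRMED
            elif lower < level:
                status[g] = REJECTED

    history = pd.DataFrame(history_rows, columns=genes).reset_index(drop=True)
    return BorutaResult(
        status=status,
        importance_history=history,
        shadow_max_history=shadow_max_history,
        hits=hits,
    )


def confirmed_features(r: BorutaResult) -> list[str]:
    """Genes with status ``confirmed``, in the input gene order."""
    return r.status.index[r.status == CONFIRMED].tolist()
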