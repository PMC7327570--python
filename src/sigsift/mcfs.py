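"""Monte-Carlo Feature Selection: relative-importance ranking over projection trees.

The idea: draw ``s`` random subsets ("projections") of ``m`` of the ``d``
candidate genes, grow ``t`` classification trees per subset (each on a fresh
stratified train/evaluation split), and aggregate, per gene ``g``, over all
``s*t`` trees

    RI(g) = sum_tau (wAcc_tau)^u * sum_{nodes n of tau splitting on g}
            IG(n) * (samples at n / samples in tau)^v

where ``wAcc`` is the tree's class-balanced accuracy on its held-out
samples, ``IG`` the entropy information gain of the node's split, and ``u``,
``v`` exponents weighting tree quality and node coverage.  A gene used by
many accurate trees, near their roots, scores high; a gene never chosen
scores zero.  Features are then ranked by descending RI, and a
label-permutation null decides how deep into the ranking the signal
plausibly extends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .matrix import validate_matrix, validate_labels

__all__ = [
    "MCFSParams",
    "NodeRecord",
    "TreeEvaluation",
    "RankedFeatureList",
    "sample_feature_subsets",
    "build_projection_trees",
    "relative_importance",
    "rank_features",
    "run_mcfs",
    "top_ranking_cutoff",
]


@dataclass(frozen=True)
class MCFSParams:
    """Ensemble-size and weighting parameters.

    ``m`` and ``s`` default to None, meaning "derive from the number of
    candidate genes d": m = max(ceil(0.05*d), 5) and s = ceil(15*d/m), so
    every gene lands in about 15 subsets on average.
    """

    m: int | None = None
    s: int | None = None
    t: int = 5
    u: float = 1.0
    v: float = 1.0
    split_fraction: float = 0.66
    seed: int = 0

    def __post_init__(self):
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if self.u < 0 or self.v < 0:
            raise ValueError("u and v must be non-negative")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1")
        if self.s is not None and self.s < 1:
            raise ValueError("s must be >= 1")

    def resolve(self, d: int) -> tuple[int, int]:
        """Concrete (m, s) for a d-gene input."""
        m = self.m if self.m is not None else max(math.ceil(0.05 * d), 5)
        m = min(m, d)
        s = self.s if self.s is not None else math.ceil(15 * d / m)
        return m, s


@dataclass(frozen=True)
class NodeRecord:
    gene_id: str
    info_gain: float
    n_node: int


@dataclass(frozen=True)
class TreeEvaluation:
    tree_id: int
    w_acc: float
    tree_n: int
    node_records: tuple[NodeRecord, ...] = field(repr=False)


@dataclass(frozen=True)
class RankedFeatureList:
    """Genes in descending relative importance: entry i is the i-th best feature."""

    entries: tuple[tuple[str, float], ...]

    @property
    def N(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def top(self, k: int) -> list[str]:
        if not 0 <= k <= self.N:
            raise ValueError(f"k must lie in [0, {self.N}]")
        return self.gene_ids[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.N + 1),
                "gene_id": self.gene_ids,
                "RI": [ri for _, ri in self.entries],
            }
        )


def sample_feature_subsets(gene_ids: list[str], p: MCFSParams) -> list[list[str]]:
    """Draw s subsets of m distinct genes, uniformly without replacement."""
    d = len(gene_ids)
    m, s = p.resolve(d)
    if p.m is not None and p.m > d:
        raise ValueError(f"m={p.m} exceeds the number of candidate genes d={d}")
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 0]))
    gene_arr = np.asarray(gene_ids, dtype=object)
    return [list(rng.choice(gene_arr, size=m, replace=False)) for _ in range(s)]


def _stratified_split(y: np.ndarray, frac: float, rng: np.random.Generator):
    """Train/holdout indices keeping every class on both sides."""
    train_idx: list[np.ndarray] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if len(members) < 2:
            raise ValueError(
                f"class {cls!r} has {len(members)} sample(s); "
                "stratified splitting needs >= 2 per class"
            )
        n_train = int(np.clip(round(frac * len(members)), 1, len(members) - 1))
        train_idx.append(rng.choice(members, size=n_train, replace=False))
    train = np.sort(np.concatenate(train_idx))
    holdout = np.setdiff1d(np.arange(len(y)), train)
    return train, holdout


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-class recall over the classes present in y_true."""
    recalls = []
    for cls in np.unique(y_true):
        mask = y_true == cls
        recalls.append(float((y_pred[mask] == cls).mean()))
    return float(np.mean(recalls))


def _harvest_nodes(clf: DecisionTreeClassifier, genes: list[str]) -> tuple[NodeRecord, ...]:
    t = clf.tree_
    records = []
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        n_parent = t.weighted_n_node_samples[node]
        ig = t.impurity[node] - (
            t.weighted_n_node_samples[left] / n_parent * t.impurity[left]
            + t.weighted_n_node_samples[right] / n_parent * t.impurity[right]
        )
        records.append(
            NodeRecord(
                gene_id=genes[t.feature[node]],
                info_gain=max(float(ig), 0.0),
                n_node=int(round(n_parent)),
            )
        )
    return tuple(records)


def build_projection_trees(
    m_matrix: pd.DataFrame,
    labels: pd.Series,
    p: MCFSParams,
    seed: int | None = None,
    first_tree_id: int = 0,
) -> list[TreeEvaluation]:
    """Grow ``p.t`` entropy trees on one feature subset and evaluate each.

    Every tree trains on a fresh stratified ``split_fraction`` draw and is
    scored by class-balanced accuracy on the held-out remainder; all
    internal nodes are recorded with their splitting gene, information gain
    and sample count.
    """
    m_matrix = validate_matrix(m_matrix)
    labels = validate_labels(labels, m_matrix)
    if m_matrix.shape[0] == 0:
        raise ValueError("feature subset is empty")
    if labels.nunique() < 2:
        raise ValueError("need >= 2 classes to build classification trees")
    genes = list(m_matrix.index)
    X = m_matrix.to_numpy().T
    y = labels.to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([p.seed if seed is None else seed, 1]))

    evals = []
    for j in range(p.t):
        train, hold = _stratified_split(y, p.split_fraction, rng)
        clf = DecisionTreeClassifier(
            criterion="entropy",
            min_samples_split=2,
            random_state=int(rng.integers(2**31)),
        )
        clf.fit(X[train], y[train])
        w_acc = _balanced_accuracy(y[hold], clf.predict(X[hold]))
        evals.append(
            TreeEvaluation(
                tree_id=first_tree_id + j,
                w_acc=w_acc,
                tree_n=len(train),
                node_records=_harvest_nodes(clf, genes),
            )
        )
    return evals


def relative_importance(
    evals: list[TreeEvaluation], p: MCFSParams, gene_ids: list[str] | None = None
) -> dict[str, float]:
    """Aggregate per-gene RI over all trees.

    RI(g) = sum over trees of wAcc^u * sum over g's nodes of
    IG * (node count / tree size)^v.  Genes listed in ``gene_ids`` but never
    split on get RI = 0.
    """
    ri: dict[str, float] = {g: 0.0 for g in gene_ids} if gene_ids else {}
    for ev in evals:
        weight = ev.w_acc**p.u
        for rec in ev.node_records:
            term = weight * rec.info_gain * (rec.n_node / ev.tree_n) ** p.v
            ri[rec.gene_id] = ri.get(rec.gene_id, 0.0) + term
    return ri


def rank_features(ri: dict[str, float]) -> RankedFeatureList:
    """Sort descending by RI, ties broken lexicographically by gene ID."""
    if not ri:
        raise ValueError("no relative-importance scores to rank")
    entries = tuple(sorted(ri.items(), key=lambda kv: (-kv[1], kv[0])))
    return RankedFeatureList(entries=entries)


def run_mcfs(
    m: pd.DataFrame, labels: pd.Series, p: MCFSParams
) -> tuple[RankedFeatureList, list[TreeEvaluation]]:
    """Full MCFS pass: subsets -> s*t projection trees -> RI -> ranking."""
    m = validate_matrix(m)
    labels = validate_labels(labels, m)
    subsets = sample_feature_subsets(list(m.index), p)
    evals: list[TreeEvaluation] = []
    sub_seeds = np.random.SeedSequence([p.seed, 2]).generate_state(len(subsets))
    for i, subset in enumerate(subsets):
        evals.extend(
            build_projection_trees(
                m.loc[subset],
                labels,
                p,
                seed=int(sub_seeds[i] % (2**31)),
                first_tree_id=i * p.t,
            )
        )
    ri = relative_importance(evals, p, gene_ids=list(m.index))
    return rank_features(ri), evals


def top_ranking_cutoff(
    ranked: RankedFeatureList,
    m: pd.DataFrame,
    labels: pd.Series,
    p: MCFSParams,
    n_perm: int = 20,
    quantile: float = 0.95,
    fixed_k: int | None = None,
) -> int:
    """How deep the ranking stays above a permutation null.

    Re-runs the RI computation ``n_perm`` times on label-permuted data, takes
    the ``quantile`` of the resulting maximal-RI distribution as threshold,
    and returns the largest k such that every gene ranked <= k scores above
    it.  ``fixed_k`` overrides the estimate (e.g. to replicate an external
    choice of list length).
    """
    if fixed_k is not None:
        if not 0 <= fixed_k <= ranked.N:
            raise ValueError(f"fixed_k must lie in [0, {ranked.N}]")
        return fixed_k
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    m = validate_matrix(m)
    labels = validate_labels(labels, m)
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 3]))
    maxima = []
    for b in range(n_perm):
        permuted = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index, name=labels.name
        )
        perm_params = MCFSParams(
            m=p.m, s=p.s, t=p.t, u=p.u, v=p.v,
            split_fraction=p.split_fraction, seed=int(rng.integers(2**31)),
        )
        perm_ranked, _ = run_mcfs(m, permuted, perm_params)
        maxima.append(perm_ranked.entries[0][1])
    threshold = float(np.quantile(maxima, quantile))
    k = 0
    for _, ri in ranked.entries:
        if ri > threshold:
            k += 1
        else:
            break
    return k
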