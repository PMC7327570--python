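"""Hypergeometric over-representation analysis of a gene signature.

Given a query gene list (e.g. the selected signature), a collection of
annotated gene sets in GMT format, and a background universe (by default the
genes that entered the analysis, not the whole genome), each set is tested
for over-representation with the upper-tail hypergeometric probability
P(X >= k) of drawing at least the observed overlap by chance, followed by
Benjamini-Hochberg adjustment across the collection.  Set members outside
the universe are dropped so the 2x2 margins stay consistent; FDR is
computed within one collection at a time, so test KEGG and each GO branch
in separate calls if per-category adjustment is wanted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeometric_p",
    "bh_fdr",
    "enrich",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus an optional background universe."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: tuple[str, ...] | None = None


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description, members.

    Duplicate members within a set are collapsed (first occurrence kept).
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need name, description, >=1 member")
            name, desc, members = parts[0], parts[1], parts[2:]
            members = [g for g in members if g]
            sets[name] = tuple(dict.fromkeys(members))
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def hypergeometric_p(overlap: int, set_size: int, query_size: int, universe_size: int) -> float:
    """Upper-tail P(X >= overlap), X ~ Hypergeometric(universe, set, query draws)."""
    k, K, n, N = overlap, set_size, query_size, universe_size
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("set and query sizes must lie within the universe size")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap {k} exceeds min(set_size, query_size) = {min(K, n)}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: list[str],
    gsc: GeneSetCollection,
    universe: list[str] | None = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test every set in the collection for over-representation of ``query``.

    Returns one row per set — overlap, margin sizes, raw p, BH FDR and a
    significance flag — sorted ascending by FDR then set name.  Query genes
    outside the universe are dropped with a logged warning.
    """
    if universe is None:
        universe = list(gsc.universe) if gsc.universe is not None else None
    if not universe:
        raise ValueError("an enrichment universe is required and must be non-empty")
    uni = set(universe)
    query_in = [g for g in dict.fromkeys(query) if g in uni]
    dropped = len(set(query)) - len(query_in)
    if dropped:
        logger.warning("%d query gene(s) outside the universe were dropped", dropped)
    qset = set(query_in)

    rows = []
    for name, members in gsc.sets.items():
        members_in = [g for g in members if g in uni]
        k = len(qset.intersection(members_in))
        p = hypergeometric_p(k, len(members_in), len(qset), len(uni))
        rows.append(
            {
                "set_name": name,
                "description": gsc.descriptions.get(name, ""),
                "overlap_count": k,
                "set_size_in_universe": len(members_in),
                "query_size_in_universe": len(qset),
                "universe_size": len(uni),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    table["significant"] = table["fdr"] < fdr_threshold
    return table.sort_values(["fdr", "set_name"], kind="stable").reset_index(drop=True)
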