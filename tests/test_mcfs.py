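"""Projection-tree ensembles and the relative-importance formula."""

import numpy as np
import pandas as pd
import pytest

from sigsift import (
    MCFSParams,
    NodeRecord,
    SyntheticConfig,
    TreeEvaluation,
    build_projection_trees,
    generate_dataset,
    rank_features,
    relative_importance,
    run_mcfs,
    sample_feature_subsets,
    top_ranking_cutoff,
)

FAST = MCFSParams(m=10, s=60, t=3, seed=21)


def make_eval(tree_id, w_acc, tree_n, nodes):
    return TreeEvaluation(
        tree_id=tree_id,
        w_acc=w_acc,
        tree_n=tree_n,
        node_records=tuple(NodeRecord(g, ig, n) for g, ig, n in nodes),
    )


# a hand-constructed two-tree instance; expected RI values summed term by
# term on paper, frozen here
TWO_TREES = [
    make_eval(0, 0.8, 10, [("gA", 0.5, 10), ("gB", 0.3, 4)]),
    make_eval(1, 0.5, 8, [("gA", 0.2, 8), ("gA", 0.1, 2)]),
]


class TestRelativeImportance:
    def test_two_tree_hand_oracle_u1_v1(self):
        ri = relative_importance(TWO_TREES, MCFSParams(m=2, s=1, t=2, u=1, v=1))
        # gA: 0.8*0.5*1 + 0.5*(0.2*1 + 0.1*0.25) = 0.5125
        # gB: 0.8*0.3*0.4 = 0.096
        assert ri["gA"] == pytest.approx(0.5125, abs=1e-12)
        assert ri["gB"] == pytest.approx(0.096, abs=1e-12)

    def test_two_tree_hand_oracle_u2_v_half(self):
        ri = relative_importance(TWO_TREES, MCFSParams(m=2, s=1, t=2, u=2, v=0.5))
        # gA: 0.64*0.5 + 0.25*(0.2 + 0.1*sqrt(0.25)) = 0.3825
        # gB: 0.64*0.3*sqrt(0.4)
        assert ri["gA"] == pytest.approx(0.3825, abs=1e-12)
        assert ri["gB"] == pytest.approx(0.192 * np.sqrt(0.4), abs=1e-12)

    def test_u0_v0_reduces_to_plain_information_gain_sum(self):
        ri = relative_importance(TWO_TREES, MCFSParams(m=2, s=1, t=2, u=0, v=0))
        assert ri["gA"] == pytest.approx(0.5 + 0.2 + 0.1, abs=1e-12)
        assert ri["gB"] == pytest.approx(0.3, abs=1e-12)

    def test_single_forced_arithmetic_node(self):
        ev = make_eval(0, 1.0, 6, [("g", 0.5, 6)])
        ri = relative_importance([ev], MCFSParams(m=1, s=1, t=1, u=1, v=1))
        assert ri["g"] == pytest.approx(0.5, abs=1e-15)

    def test_unused_gene_gets_zero(self):
        ri = relative_importance(
            TWO_TREES, MCFSParams(m=2, s=1, t=2), gene_ids=["gA", "gB", "gC"]
        )
        assert ri["gC"] == 0.0

    def test_additive_over_disjoint_tree_sets(self):
        p = MCFSParams(m=2, s=1, t=2, u=1.5, v=0.7)
        joint = relative_importance(TWO_TREES, p)
        first = relative_importance(TWO_TREES[:1], p)
        second = relative_importance(TWO_TREES[1:], p)
        for g in joint:
            assert joint[g] == pytest.approx(
                first.get(g, 0.0) + second.get(g, 0.0), abs=1e-12
            )


class TestSampleFeatureSubsets:
    def test_m_equals_d_forces_full_subset(self):
        subsets = sample_feature_subsets(["a", "b", "c"], MCFSParams(m=3, s=4, t=1))
        assert all(sorted(sub) == ["a", "b", "c"] for sub in subsets)

    def test_shapes_and_reproducibility(self):
        p = MCFSParams(m=2, s=3, t=1, seed=17)
        genes = ["a", "b", "c", "d", "e"]
        s1 = sample_feature_subsets(genes, p)
        s2 = sample_feature_subsets(genes, p)
        assert s1 == s2
        assert len(s1) == 3
        assert all(len(set(sub)) == 2 for sub in s1)

    def test_uniform_inclusion_frequency(self):
        p = MCFSParams(m=1, s=400, t=1, seed=19)
        subsets = sample_feature_subsets(["a", "b"], p)
        count_a = sum(sub == ["a"] for sub in subsets)
        # binomial(400, 1/2): 4 sigma around 200
        assert abs(count_a - 200) < 4 * np.sqrt(100)

    def test_m_larger_than_d_rejected(self):
        with pytest.raises(ValueError, match="m="):
            sample_feature_subsets(["a", "b"], MCFSParams(m=3, s=1, t=1))


class TestBuildProjectionTrees:
    def test_perfect_gene_reaches_wacc_one(self):
        n = 20
        labels = pd.Series(
            ["x"] * (n // 2) + ["y"] * (n // 2), index=[f"s{i}" for i in range(n)]
        )
        m = pd.DataFrame(
            [np.r_[np.zeros(n // 2), np.full(n // 2, 10.0)]], index=["sep"],
            columns=labels.index,
        )
        evals = build_projection_trees(m, labels, MCFSParams(m=1, s=1, t=4, seed=23))
        assert all(ev.w_acc == 1.0 for ev in evals)

    def test_root_node_count_equals_training_size(self):
        cfg = SyntheticConfig(
            class_sizes=(12, 12), n_genes=8, n_informative=2, effect_size=3, seed=29
        )
        m, labels, _ = generate_dataset(cfg)
        evals = build_projection_trees(m, labels, MCFSParams(m=8, s=1, t=5, seed=29))
        for ev in evals:
            assert ev.node_records, "every tree should split at least once"
            assert max(r.n_node for r in ev.node_records) == ev.tree_n
            assert all(r.info_gain >= 0 for r in ev.node_records)
            assert 0 <= ev.w_acc <= 1

    def test_shuffled_labels_give_chance_level_wacc(self):
        rng = np.random.default_rng(31)
        n = 40
        accs = []
        for rep in range(20):
            m = pd.DataFrame(
                rng.normal(size=(3, n)), index=["a", "b", "c"],
                columns=[f"s{i}" for i in range(n)],
            )
            labels = pd.Series(
                rng.permutation(np.repeat(["x", "y"], n // 2)), index=m.columns
            )
            evals = build_projection_trees(
                m, labels, MCFSParams(m=3, s=1, t=5, seed=rep)
            )
            accs.extend(ev.w_acc for ev in evals)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.08)

    def test_stratification_impossible_rejected(self, rng):
        m = pd.DataFrame(
            np.random.default_rng(1).normal(size=(3, 4)),
            index=["a", "b", "c"], columns=[f"s{i}" for i in range(4)],
        )
        labels = pd.Series(["x", "x", "x", "y"], index=m.columns)
        with pytest.raises(ValueError, match="stratified"):
            build_projection_trees(m, labels, MCFSParams(m=3, s=1, t=1))


class TestRanking:
    def test_descending_order_with_lexicographic_ties(self):
        ranked = rank_features({"b": 0.9, "a": 0.1, "c": 0.9, "d": 0.9})
        assert ranked.gene_ids == ["b", "c", "d", "a"]
        ris = [ri for _, ri in ranked.entries]
        assert ris == sorted(ris, reverse=True)

    def test_all_equal_scores_fall_back_to_gene_order(self):
        ranked = rank_features({"z": 1.0, "m": 1.0, "a": 1.0})
        assert ranked.gene_ids == ["a", "m", "z"]

    def test_full_run_is_deterministic_and_ranks_planted_genes_on_top(
        self, small_dataset
    ):
        m, labels, truth = small_dataset
        ranked1, evals = run_mcfs(m, labels, FAST)
        ranked2, _ = run_mcfs(m, labels, FAST)
        assert ranked1.entries == ranked2.entries
        assert len(evals) == 60 * 3
        ranks = {g: i + 1 for i, (g, _) in enumerate(ranked1.entries)}
        planted = [ranks[g] for g in truth.informative_genes]
        assert np.median(planted) <= ranked1.N / 10


class TestTopRankingCutoff:
    def test_fixed_k_override(self, small_dataset):
        m, labels, _ = small_dataset
        ranked, _ = run_mcfs(m, labels, FAST)
        assert top_ranking_cutoff(ranked, m, labels, FAST, fixed_k=42) == 42

    def test_invalid_n_perm_rejected(self, small_dataset):
        m, labels, _ = small_dataset
        ranked, _ = run_mcfs(m, labels, FAST)
        with pytest.raises(ValueError, match="n_perm"):
            top_ranking_cutoff(ranked, m, labels, FAST, n_perm=0)

    def test_planted_genes_survive_cutoff_and_noise_does_not(self):
        cfg = SyntheticConfig(
            class_sizes=(15, 15, 15, 15),
            n_genes=80,
            n_informative=8,
            effect_size=4,
            seed=37,
        )
        m, labels, truth = generate_dataset(cfg)
        p = MCFSParams(m=10, s=300, t=3, seed=37)
        ranked, _ = run_mcfs(m, labels, p)
        k = top_ranking_cutoff(ranked, m, labels, p, n_perm=10)
        assert k >= 8
        assert set(truth.informative_genes) <= set(ranked.top(k))

        null_cfg = SyntheticConfig(
            class_sizes=(15, 15, 15, 15), n_genes=40, n_informative=0, seed=41
        )
        mn, ln, _ = generate_dataset(null_cfg)
        pn = MCFSParams(m=8, s=40, t=3, seed=41)
        ranked_n, _ = run_mcfs(mn, ln, pn)
        k_null = top_ranking_cutoff(ranked_n, mn, ln, pn, n_perm=10)
        assert k_null <= 2
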