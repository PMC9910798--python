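"""Size factors, the pairwise negative-binomial test, double correction,
rank scores and expression clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from seednet import dea
from seednet.gct import CountMatrix
from seednet.hclust import cut_max_no_singletons, linkage_to_newick


def _nb(rng, mu, alpha, size):
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mu), size)


class TestSizeFactors:
    def test_duplicate_columns_give_unit_factors(self):
        column = np.array([5, 10, 20, 40])
        counts = np.stack([column, column], axis=1)
        np.testing.assert_allclose(dea.estimate_size_factors(counts), [1.0, 1.0])

    def test_doubled_column_ratio_exactly_two(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(100, 50) + 1
        counts = np.stack([col, 2 * col], axis=1)
        factors = dea.estimate_size_factors(counts)
        assert factors[1] / factors[0] == pytest.approx(2.0, abs=1e-12)

    def test_matches_per_gene_ratio_median_oracle(self):
        rng = np.random.default_rng(1)
        # odd gene count: the median is an exact order statistic, so the
        # linear-space ratio median equals the log-space one
        counts = _nb(rng, 100.0, 0.1, (201, 12)) + 1
        factors = dea.estimate_size_factors(counts)
        geomean = np.exp(np.log(counts).mean(axis=1))
        oracle = np.median(counts / geomean[:, None], axis=0)
        np.testing.assert_allclose(factors, oracle, atol=1e-12)

    def test_matches_reference_deseq_implementation(self):
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(2)
        counts = _nb(rng, 80.0, 0.1, (300, 10)) + 1
        ours = dea.estimate_size_factors(counts)
        _, theirs = deseq2_norm(pd.DataFrame(counts.T))  # samples x genes
        np.testing.assert_allclose(ours, np.asarray(theirs), rtol=1e-10)

    def test_no_all_nonzero_gene_raises(self):
        counts = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="nonzero"):
            dea.estimate_size_factors(counts)


class TestNbPairwiseTest:
    def test_identical_groups_null_result(self):
        counts = np.tile(np.array([50, 60, 70, 80]), (5, 1))
        res = dea.nb_pairwise_test(counts, counts, np.ones(4), np.ones(4))
        np.testing.assert_allclose(res["lfc"], 0.0)
        assert (res["pvalue"] > 0.9).all()

    def test_zero_both_groups_untestable(self):
        zeros = np.zeros((1, 5))
        res = dea.nb_pairwise_test(zeros, zeros, np.ones(5), np.ones(5))
        assert res.loc[0, "untestable"]
        assert res.loc[0, "pvalue"] == 1.0
        assert res.loc[0, "lfc"] == 0.0

    def test_single_sample_group_rejected(self):
        counts = np.ones((3, 1))
        with pytest.raises(ValueError, match="2 samples"):
            dea.nb_pairwise_test(counts, counts, np.ones(1), np.ones(1))

    def test_lfc_sign_follows_normalized_means(self):
        rng = np.random.default_rng(3)
        a = _nb(rng, 400.0, 0.05, (50, 10))
        b = _nb(rng, 100.0, 0.05, (50, 10))
        res = dea.nb_pairwise_test(a, b, np.ones(10), np.ones(10))
        assert (res["lfc"] > 0).all()

    def test_planted_fourfold_shift_power(self):
        """4-fold shift at n=30+30 stays significant after BH x Bonferroni(105)."""
        rng = np.random.default_rng(4)
        reps, hits = 40, 0
        for _ in range(reps):
            mu = float(rng.uniform(50, 200))
            a = _nb(rng, 4 * mu, 0.1, (1, 30))
            b = _nb(rng, mu, 0.1, (1, 30))
            res = dea.nb_pairwise_test(a, b, np.ones(30), np.ones(30))
            hits += res.loc[0, "pvalue"] * 105 < 0.05  # worst-case correction
        assert hits / reps >= 0.9


class TestCorrectPairwise:
    @pytest.mark.parametrize(
        "p_pair,n_pairs,expected,significant",
        [
            (0.01, 105, 1.0, False),
            (1e-6, 105, 1.05e-4, True),
            (0.03, 1, 0.03, True),
        ],
    )
    def test_bonferroni_arithmetic(self, p_pair, n_pairs, expected, significant):
        frame = pd.DataFrame({"padj_pair": [p_pair]})
        out = dea.correct_pairwise(frame, n_pairs)
        assert out.loc[0, "padj_final"] == pytest.approx(expected)
        assert bool(out.loc[0, "padj_final"] < 0.05) is significant


def _random_verdict_table(rng, genes, tissues, p_sig=0.4):
    """Random signed significance verdicts as a long-form DEA table."""
    rows = []
    for g in genes:
        for i, a in enumerate(tissues):
            for b in tissues[i + 1:]:
                significant = rng.random() < p_sig
                direction = rng.choice([-1.0, 1.0])
                rows.append(
                    {
                        "gene": g, "tissue_a": a, "tissue_b": b,
                        "lfc": direction * rng.uniform(0.5, 3),
                        "significant": significant,
                    }
                )
    return pd.DataFrame(rows)


class TestRankScores:
    def test_no_significant_pairs_all_zero(self):
        rng = np.random.default_rng(0)
        table = _random_verdict_table(rng, ["g1", "g2"], ["A", "B", "C"], p_sig=0.0)
        scores = dea.rank_scores(table, ["A", "B", "C"])
        assert (scores.to_numpy() == 0).all()

    def test_uniquely_high_gene_scores_t_minus_one(self):
        tissues = [f"T{i:02d}" for i in range(15)]
        rows = []
        for i, a in enumerate(tissues):
            for b in tissues[i + 1:]:
                rows.append(
                    {"gene": "g", "tissue_a": a, "tissue_b": b,
                     "lfc": 1.0 if a == "T00" else (-1.0 if b == "T00" else 0.5),
                     "significant": "T00" in (a, b)}
                )
        scores = dea.rank_scores(pd.DataFrame(rows), tissues)
        assert scores.loc["g", "T00"] == 14
        assert scores.drop(columns="T00").loc["g"].sum() == 0

    def test_matches_ordered_pair_enumeration_on_random_verdicts(self):
        """Oracle: count wins per tissue by looping over all ordered pairs."""
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(10)]
        tissues = [f"T{i}" for i in range(6)]
        for _ in range(25):
            table = _random_verdict_table(rng, genes, tissues)
            scores = dea.rank_scores(table, tissues)
            oracle = pd.DataFrame(0, index=genes, columns=tissues)
            for row in table.itertuples():
                if row.significant:
                    winner = row.tissue_a if row.lfc > 0 else row.tissue_b
                    oracle.loc[row.gene, winner] += 1
            pd.testing.assert_frame_equal(scores, oracle, check_names=False)

    def test_tissue_relabeling_equivariance(self):
        rng = np.random.default_rng(7)
        tissues = ["A", "B", "C", "D"]
        table = _random_verdict_table(rng, ["g1", "g2", "g3"], tissues)
        scores = dea.rank_scores(table, tissues)
        relabel = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        flipped = table.copy()
        flipped["tissue_a"] = flipped["tissue_a"].map(relabel)
        flipped["tissue_b"] = flipped["tissue_b"].map(relabel)
        scores2 = dea.rank_scores(flipped, list("WXYZ"))
        np.testing.assert_array_equal(scores.to_numpy(), scores2.to_numpy())

    def test_rank_matrix_bounds(self):
        rng = np.random.default_rng(9)
        tissues = [f"T{i}" for i in range(6)]
        table = _random_verdict_table(rng, ["g"], tissues, p_sig=1.0)
        scores = dea.rank_scores(table, tissues)
        T = len(tissues)
        assert scores.to_numpy().max() <= T - 1
        assert scores.loc["g"].sum() <= T * (T - 1) / 2

    def test_duplicated_significant_pair_rejected(self):
        table = pd.DataFrame(
            {
                "gene": ["g", "g"], "tissue_a": ["A", "A"], "tissue_b": ["B", "B"],
                "lfc": [1.0, -1.0], "significant": [True, True],
            }
        )
        with pytest.raises(ValueError, match="inconsistent"):
            dea.rank_scores(table, ["A", "B"])


class TestHighSpecificity:
    def test_threshold_inclusive_at_twelve(self):
        matrix = pd.DataFrame(
            {f"T{i:02d}": 0 for i in range(15)},
            index=["g12", "g11"],
        )
        matrix.loc["g12", "T03"] = 12
        matrix.loc["g11", "T03"] = 11
        hits = dea.high_specificity_set(matrix)
        assert hits["T03"] == ["g12"]
        strict = dea.high_specificity_set(matrix, strict=True)
        assert strict["T03"] == []

    def test_all_zero_matrix_empty_lists(self):
        matrix = pd.DataFrame(0, index=["g"], columns=[f"T{i:02d}" for i in range(15)])
        assert all(v == [] for v in dea.high_specificity_set(matrix).values())

    def test_threshold_rescales_with_tissue_count(self):
        # T=8: ceil(7 * 12/14) = 6
        matrix = pd.DataFrame(0, index=["g"], columns=[f"T{i}" for i in range(8)])
        matrix.loc["g", "T0"] = 6
        assert dea.high_specificity_set(matrix)["T0"] == ["g"]
        matrix.loc["g", "T0"] = 5
        assert dea.high_specificity_set(matrix)["T0"] == []


class TestExpressionClustering:
    def test_identical_tissue_columns_merge_at_height_zero(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(5, 1, 20)
        matrix = pd.DataFrame(
            {"t1": profile, "t2": profile, "t3": profile + 3, "t4": profile - 2},
            index=[f"g{i}" for i in range(20)],
        )
        clustering = dea.cluster_expression(matrix)
        assert clustering.tissue_linkage[0, 2] == pytest.approx(0.0)
        merged = {int(clustering.tissue_linkage[0, 0]),
                  int(clustering.tissue_linkage[0, 1])}
        assert merged == {0, 1}  # the identical pair merges first

    def test_four_gene_pairing_matches_hand_distances(self):
        matrix = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.2, 5.0]],
            index=["a", "b", "c", "d"], columns=["t1", "t2"],
        )
        with pytest.warns(UserWarning, match="fewer than 3 tissues"):
            clustering = dea.cluster_expression(matrix)
        clusters = {frozenset(c) for c in clustering.clusters}
        assert clusters == {frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_planted_tissue_clade_recovered(self, counts_sim, default_config):
        from seednet.hclust import contains_clade
        matrix = counts_sim.matrix
        sf = dea.estimate_size_factors(matrix.counts)
        means = dea.normalized_mean_matrix(matrix, sf)
        clustering = dea.cluster_expression(means.loc[
            [g for g in matrix.genes if g in set(default_config.interactor_symbols)
             or g == "SEED1"]
        ])
        assert contains_clade(
            clustering.tissue_linkage, list(means.columns),
            set(default_config.planted_clade),
        )

    def test_seed_cluster_returns_containing_cluster(self):
        clusters = [{"a", "b"}, {"SEED1", "c"}]
        assert dea.seed_cluster(clusters, "SEED1") == {"SEED1", "c"}
        with pytest.raises(KeyError):
            dea.seed_cluster(clusters, "missing")


def _oracle_cut(Z, leaf_names):
    """Exhaustive cut enumeration with a hand-rolled union-find."""
    n = Z.shape[0] + 1
    heights = sorted(set(Z[:, 2]))
    candidates = heights + [heights[-1] + 1]
    best = None
    for h in candidates:
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        clusters_of = {i: {i} for i in range(n)}
        next_id = n
        node_members = {i: {i} for i in range(n)}
        for a, b, height, _ in Z:
            if height >= h - 1e-12:
                break
            members = node_members[int(a)] | node_members[int(b)]
            node_members[next_id] = members
            next_id += 1
        # derive partition: members of applied merges
        applied = [row for row in Z if row[2] < h - 1e-12]
        groups = {i: {i} for i in range(n)}
        ids = {i: i for i in range(n)}
        nid = n
        for a, b, height, _ in applied:
            ga, gb = int(a), int(b)
            groups[nid] = groups.pop(ga) | groups.pop(gb)
            nid += 1
        partition = [frozenset(leaf_names[i] for i in g) for g in groups.values()]
        if min(len(p) for p in partition) < 2:
            continue
        key = (len(partition), -h)
        if best is None or key > best[0]:
            best = (key, set(partition), h)
    if best is None:
        return {frozenset(leaf_names)}, float(max(heights))
    return best[1], best[2]


class TestCutMaxNoSingletons:
    def test_four_tight_pairs_give_four_clusters(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]])
        points = np.concatenate([c + rng.normal(0, 0.01, (2, 2)) for c in centers])
        Z = linkage(points, method="complete")
        clusters, _ = cut_max_no_singletons(Z)
        assert len(clusters) == 4
        assert all(len(c) == 2 for c in clusters)

    def test_chain_tree_collapses_to_root(self):
        # 1-D geometric chain: every cut isolates the next leaf
        points = np.array([[2.0**i] for i in range(6)])
        Z = linkage(points, method="single")
        clusters, _ = cut_max_no_singletons(Z)
        assert len(clusters) == 1

    def test_two_leaves_single_pair(self):
        Z = linkage(np.array([[0.0], [1.0]]), method="complete")
        clusters, _ = cut_max_no_singletons(Z, ["x", "y"])
        assert clusters == [{"x", "y"}]

    @pytest.mark.parametrize("method", ["complete", "average"])
    def test_matches_exhaustive_enumeration(self, method):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 13))
            points = rng.normal(size=(n, 3))
            Z = linkage(points, method=method)
            names = [f"L{i}" for i in range(n)]
            got, _ = cut_max_no_singletons(Z, names)
            want, _ = _oracle_cut(Z, names)
            assert {frozenset(c) for c in got} == want


def test_newick_export_round_trips_through_dendropy():
    import dendropy

    rng = np.random.default_rng(0)
    points = rng.normal(size=(6, 2))
    Z = linkage(points, method="average")
    names = [f"leaf{i}" for i in range(6)]
    text = linkage_to_newick(Z, names)
    tree = dendropy.Tree.get(data=text, schema="newick")
    assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set(names)
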