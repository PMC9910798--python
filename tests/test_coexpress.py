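"""Per-tissue co-expression, the resampling reference null, Tukey rank
scores and co-expression clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seednet import coexpress
from seednet.gct import CountMatrix


def _matrix_from_counts(counts: np.ndarray, genes, tissue="t") -> CountMatrix:
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        pd.DataFrame({"tissue": [tissue] * len(samples)}, index=samples),
    )


class TestTissueCoexpression:
    def test_exact_linear_dependence_gives_r_one(self):
        rng = np.random.default_rng(0)
        seed = rng.poisson(100, 30).astype(float)
        counts = np.stack([seed, 2 * seed])
        matrix = _matrix_from_counts(counts, ["SEED", "G1"])
        col = coexpress.tissue_coexpression(matrix, "SEED", ["G1"], "t")
        assert col.loc["G1", "r"] == pytest.approx(1.0)
        assert col.loc["G1", "p_bonferroni"] == pytest.approx(0.0)

    def test_independent_interactor_bounded_null_r(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(60):
            seed = rng.poisson(100, 50).astype(float)
            other = rng.poisson(100, 50).astype(float)
            matrix = _matrix_from_counts(np.stack([seed, other]), ["SEED", "G1"])
            col = coexpress.tissue_coexpression(matrix, "SEED", ["G1"], "t")
            hits += abs(col.loc["G1", "r"]) < 0.4
        assert hits / 60 >= 0.95

    def test_zero_variance_interactor_recorded_missing(self):
        rng = np.random.default_rng(2)
        seed = rng.poisson(100, 20).astype(float)
        flat = np.full(20, 7.0)
        matrix = _matrix_from_counts(np.stack([seed, flat]), ["SEED", "G1"])
        col = coexpress.tissue_coexpression(matrix, "SEED", ["G1"], "t")
        assert np.isnan(col.loc["G1", "r"])
        assert not col.loc["G1", "valid"]

    def test_zero_variance_seed_is_fatal(self):
        matrix = _matrix_from_counts(
            np.stack([np.full(10, 5.0), np.arange(10.0)]), ["SEED", "G1"]
        )
        with pytest.raises(ValueError, match="zero variance"):
            coexpress.tissue_coexpression(matrix, "SEED", ["G1"], "t")

    def test_planted_latent_factor_hits_target_r(self, counts_sim, default_config):
        matrix = counts_sim.matrix
        truth = counts_sim.truth
        rs = []
        for tissue in default_config.planted_clade:
            col = coexpress.tissue_coexpression(
                matrix, "SEED1", truth.coex_set, tissue
            )
            rs.append(col["r"].mean())
        assert np.mean(rs) == pytest.approx(truth.coex_target_r, abs=0.1)


class TestReference:
    def test_single_full_size_set_equals_all_gene_correlations(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(100, (6, 25)).astype(float)
        genes = ["SEED"] + [f"G{i}" for i in range(5)]
        matrix = _matrix_from_counts(counts, genes)
        reference = coexpress.build_reference(matrix, "SEED", set_size=5,
                                              n_sets=1, rng_seed=0)
        col = coexpress.tissue_coexpression(matrix, "SEED", genes[1:], "t")
        assert np.allclose(
            np.sort(reference.per_tissue["t"]), np.sort(col["r"].to_numpy())
        )

    def test_deterministic_under_fixed_seed(self, counts_sim):
        kwargs = dict(seed_symbol="SEED1", set_size=30, n_sets=20, rng_seed=5)
        matrix = counts_sim.matrix
        one = coexpress.build_reference(matrix, kwargs["seed_symbol"],
                                        kwargs["set_size"], kwargs["n_sets"],
                                        kwargs["rng_seed"])
        two = coexpress.build_reference(matrix, kwargs["seed_symbol"],
                                        kwargs["set_size"], kwargs["n_sets"],
                                        kwargs["rng_seed"])
        for tissue in one.per_tissue:
            np.testing.assert_array_equal(one.per_tissue[tissue],
                                          two.per_tissue[tissue])

    def test_universe_smaller_than_set_size_raises(self):
        rng = np.random.default_rng(0)
        matrix = _matrix_from_counts(rng.poisson(50, (3, 10)).astype(float),
                                     ["SEED", "G1", "G2"])
        with pytest.raises(ValueError, match="smaller"):
            coexpress.build_reference(matrix, "SEED", set_size=5)

    def test_null_reference_symmetric_about_zero(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(100, (300, 60)).astype(float)
        genes = ["SEED"] + [f"G{i}" for i in range(299)]
        matrix = _matrix_from_counts(counts, genes)
        reference = coexpress.build_reference(matrix, "SEED", set_size=250,
                                              n_sets=500, rng_seed=1)
        pooled = reference.per_tissue["t"]
        assert pooled.size >= 1e5
        assert abs(pooled.mean()) < 0.02


class TestCompareToReference:
    def test_identical_samples_no_shift(self):
        rng = np.random.default_rng(5)
        sample = rng.normal(0, 0.2, 400)
        out = coexpress.compare_to_reference(sample, sample)
        assert out["median_shift"] == 0.0
        assert out["ks_pvalue"] == pytest.approx(1.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(6)
        shifted = rng.normal(0.5, 0.15, 60)
        null = rng.normal(0.0, 0.15, 5000)
        out = coexpress.compare_to_reference(shifted, null)
        assert out["median_shift"] > 0.3
        assert out["ks_pvalue"] < 0.05

    def test_resampled_reference_calibrated(self):
        rng = np.random.default_rng(7)
        null = rng.normal(0, 0.15, 20000)
        rejections = sum(
            coexpress.compare_to_reference(
                rng.choice(null, 60, replace=False), null
            )["ks_pvalue"] < 0.05
            for _ in range(200)
        )
        assert 0.01 <= rejections / 200 <= 0.10

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            coexpress.compare_to_reference(np.array([]), np.array([1.0]))


class TestCoexRankScores:
    def _table(self, columns: dict) -> coexpress.CoexTable:
        r = pd.DataFrame(columns)
        return coexpress.CoexTable(r, r * 0, r.isna())

    def test_single_distribution_scores_zero(self):
        rng = np.random.default_rng(8)
        zeros = 0
        for _ in range(20):
            r = {f"T{i}": rng.normal(0.4, 0.1, 40) for i in range(4)}
            scores = coexpress.coex_rank_scores(self._table(r))
            zeros += int((scores == 0).all())
        assert zeros / 20 >= 0.95

    def test_shifted_tissue_beats_all_others(self):
        rng = np.random.default_rng(9)
        r = {f"T{i:02d}": rng.normal(0.3, 0.1, 300) for i in range(15)}
        r["T00"] = rng.normal(0.6, 0.1, 300)
        scores = coexpress.coex_rank_scores(self._table(r))
        assert scores["T00"] == 14

    def test_matches_independent_tukey_implementation(self):
        """scipy's tukey_hsd as the independent oracle on a small fixture."""
        rng = np.random.default_rng(10)
        groups = {
            "A": rng.normal(0.2, 0.1, 10),
            "B": rng.normal(0.5, 0.1, 10),
            "C": rng.normal(0.35, 0.1, 10),
        }
        scores = coexpress.coex_rank_scores(self._table(groups))
        res = stats.tukey_hsd(*groups.values())
        names = list(groups)
        oracle = {name: 0 for name in names}
        for i in range(3):
            for j in range(i + 1, 3):
                if res.pvalue[i, j] < 0.05:
                    winner = names[i] if groups[names[i]].mean() > groups[names[j]].mean() else names[j]
                    oracle[winner] += 1
        assert scores.to_dict() == oracle

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError):
            coexpress.coex_rank_scores(self._table({"A": np.ones(3)}))


class TestClusterCoexpression:
    def _table(self, r: pd.DataFrame) -> coexpress.CoexTable:
        return coexpress.CoexTable(r, r * 0, r.isna())

    def test_two_planted_blocks_high_block_selected(self):
        rng = np.random.default_rng(11)
        tissues = [f"T{i}" for i in range(6)]
        high = pd.DataFrame(
            rng.normal(0.8, 0.03, (10, 6)), columns=tissues,
            index=[f"H{i}" for i in range(10)],
        )
        low = pd.DataFrame(
            rng.normal(0.1, 0.03, (10, 6)), columns=tissues,
            index=[f"L{i}" for i in range(10)],
        )
        clustering = coexpress.cluster_coexpression(self._table(pd.concat([high, low])))
        assert clustering.highest_cluster == set(high.index)

    def test_identical_rows_merge_at_zero_height(self):
        row = np.linspace(0.1, 0.8, 5)
        r = pd.DataFrame([row, row, row + 0.5], columns=[f"T{i}" for i in range(5)],
                         index=["a", "b", "c"])
        clustering = coexpress.cluster_coexpression(self._table(r))
        assert clustering.interactor_linkage[0, 2] == pytest.approx(0.0)

    def test_three_level_fixture_selects_highest_mean(self):
        rng = np.random.default_rng(12)
        tissues = [f"T{i}" for i in range(6)]
        blocks = []
        for label, mean in (("H", 0.8), ("M", 0.5), ("L", 0.2)):
            blocks.append(pd.DataFrame(
                rng.normal(mean, 0.02, (6, 6)), columns=tissues,
                index=[f"{label}{i}" for i in range(6)],
            ))
        clustering = coexpress.cluster_coexpression(self._table(pd.concat(blocks)))
        assert clustering.highest_cluster == set(blocks[0].index)

    def test_all_equal_matrix_single_cluster(self):
        r = pd.DataFrame(0.5, index=["a", "b", "c"], columns=["T1", "T2", "T3"])
        with pytest.warns(UserWarning, match="single cluster"):
            clustering = coexpress.cluster_coexpression(self._table(r))
        assert clustering.clusters == [{"a", "b", "c"}]

    def test_missing_values_imputed_and_flagged(self):
        rng = np.random.default_rng(13)
        r = pd.DataFrame(rng.normal(0.4, 0.1, (6, 4)),
                         index=[f"g{i}" for i in range(6)],
                         columns=[f"T{i}" for i in range(4)])
        r.iloc[0, 2] = np.nan
        clustering = coexpress.cluster_coexpression(self._table(r))
        assert clustering.imputed == ["g0"]
        assert clustering.transformed.iloc[0, 2] == pytest.approx(1.0)  # 2**0

    def test_selected_cluster_has_maximal_mean(self, counts_sim, default_config):
        """The selected set's mean beats every excluded cluster's mean."""
        from seednet import qc
        from seednet.ppi import Interactome, ScoredInteractor

        matrix, _ = qc.run_qc(counts_sim.matrix, None)
        interactome = Interactome(
            "SEED1",
            [ScoredInteractor(s, 2, 1, 3) for s in default_config.interactor_symbols],
        )
        matrix = qc.subset_to_interactome(matrix, interactome)
        coex = coexpress.coexpression_table(
            matrix, "SEED1", [g for g in matrix.genes if g != "SEED1"]
        )
        clustering = coexpress.cluster_coexpression(coex)
        selected_mean = coex.r.loc[sorted(clustering.highest_cluster)].mean().mean()
        for cluster in clustering.clusters:
            if cluster <= clustering.highest_cluster:
                continue
            assert selected_mean > coex.r.loc[sorted(cluster)].mean().mean()

    def test_score_bounds_and_permutation_equivariance(self):
        rng = np.random.default_rng(14)
        tissues = [f"T{i}" for i in range(5)]
        r = pd.DataFrame(rng.normal(0.3, 0.2, (80, 5)), columns=tissues)
        table = self._table(r)
        scores = coexpress.coex_rank_scores(table)
        assert scores.max() <= len(tissues) - 1
        perm = ["T3", "T0", "T4", "T1", "T2"]
        permuted = self._table(r[perm])
        scores_perm = coexpress.coex_rank_scores(permuted)
        for tissue in tissues:
            assert scores[tissue] == scores_perm[tissue]
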