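"""Clustering, significance pruning, and subtype label transfer."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from subtypecurves import (CohortConfig, ConfigurationError, CurveConfig,
                           DatasetDef, NumericalError, StructuralError,
                           assign_subtype_labels, cluster_centroids,
                           hclust_corr_average, normalize_counts,
                           prune_to_significant, run_unsupervised_curve,
                           sigclust_pvalue, simulate_cohort, subset_panel,
                           informative_panel)

from _oracles import upgma_cophenetic


def _expr(values, samples=None):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values,
                        index=[f"G{i}" for i in range(values.shape[0])],
                        columns=samples or [f"S{j}" for j in range(values.shape[1])])


class TestHclust:
    def test_duplicated_samples_merge_first_at_zero_height(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 5))
        X[:, 4] = X[:, 1]  # exact duplicate
        tree = hclust_corr_average(_expr(X))
        first = tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {1, 4}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_affine_transform_has_zero_dissimilarity(self):
        rng = np.random.default_rng(1)
        profile = rng.normal(size=8)
        X = np.column_stack([profile, 3.0 + 2.0 * profile,
                             rng.normal(size=8), rng.normal(size=8)])
        tree = hclust_corr_average(_expr(X))
        first = tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_upgma_on_twelve_samples(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 12))
        expr = _expr(X)
        tree = hclust_corr_average(expr)
        corr = np.corrcoef(X.T)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        oracle_coph = upgma_cophenetic(dist)
        ours_coph = squareform(cophenet(tree.linkage))
        np.testing.assert_allclose(ours_coph, oracle_coph, atol=1e-10)

    def test_constant_profile_is_named_in_the_error(self):
        X = np.ones((6, 3))
        X[:, 0] = np.arange(6)
        with pytest.raises(NumericalError, match="S1"):
            hclust_corr_average(_expr(X))

    def test_newick_export_covers_all_samples(self):
        rng = np.random.default_rng(3)
        tree = hclust_corr_average(_expr(rng.normal(size=(8, 6))))
        newick = tree.to_newick()
        assert newick.endswith(";")
        for sample in tree.sample_ids:
            assert sample in newick


class TestSigClust:
    def test_widely_separated_masses_get_minimal_pvalue(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.1, size=(10, 4)),
                       rng.normal(20 * 0.1, 0.1, size=(10, 4)) + 2.0])
        split = np.array([True] * 10 + [False] * 10)
        n_sim = 40
        p = sigclust_pvalue(X, split, n_sim=n_sim, seed=1)
        assert p <= 1 / (n_sim + 1)

    def test_null_data_pvalues_are_calibrated(self):
        """Data drawn from the fitted null itself (spherical Gaussian)
        rejects at ~alpha when the observed split is the same 2-means
        partition the simulations use."""
        rng = np.random.default_rng(5)
        n_rep = 60
        rejections = 0
        for _ in range(n_rep):
            X = rng.normal(size=(30, 10))
            p = sigclust_pvalue(X, None, n_sim=100,
                                seed=int(rng.integers(2 ** 31)))
            rejections += p <= 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01

    def test_invalid_inputs(self):
        X = np.random.default_rng(6).normal(size=(8, 3))
        with pytest.raises(ConfigurationError):
            sigclust_pvalue(X, None, n_sim=0)
        with pytest.raises(StructuralError):
            sigclust_pvalue(X, np.array([True] + [False] * 7), n_sim=10)


@pytest.fixture(scope="module")
def separated_panel():
    cohort = simulate_cohort(CohortConfig(
        n_samples=250, n_genes=500, n_informative=120, effect_size=3.0,
        lumAB_correlation=0.0, seed=42))
    expr, _ = normalize_counts(cohort.counts)
    panel, _ = subset_panel(expr, informative_panel(cohort, 50))
    return cohort, panel


class TestPruning:
    def test_alpha_zero_collapses_to_single_cluster(self, separated_panel):
        _, panel = separated_panel
        tree = hclust_corr_average(panel)
        clusters = prune_to_significant(tree, panel, alpha=0.0, n_sim=5, seed=0)
        assert clusters.nunique() == 1

    def test_five_separated_classes_give_five_clusters(self, separated_panel):
        cohort, panel = separated_panel
        tree = hclust_corr_average(panel)
        clusters = prune_to_significant(tree, panel, alpha=0.05, n_sim=50, seed=1)
        assert clusters.nunique() == 5
        cross = pd.crosstab(cohort.annotation["subtype"], clusters)
        assert (cross.gt(0).sum(axis=1) == 1).all()  # pure clusters

    def test_cluster_count_monotone_in_alpha(self, separated_panel):
        _, panel = separated_panel
        tree = hclust_corr_average(panel)
        counts = [prune_to_significant(tree, panel, alpha=a, n_sim=30,
                                       seed=2).nunique()
                  for a in (0.0, 0.01, 0.2, 1.0)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_single_gaussian_stays_one_cluster(self):
        rng = np.random.default_rng(7)
        ones = 0
        for rep in range(10):
            X = rng.normal(size=(10, 40))
            expr = _expr(X)
            tree = hclust_corr_average(expr)
            clusters = prune_to_significant(tree, expr, alpha=0.05,
                                            n_sim=50, seed=100 + rep)
            ones += clusters.nunique() == 1
        assert ones >= 9


class TestLabelTransfer:
    def _centroids(self, rng, n_genes=30):
        ref = pd.DataFrame(
            rng.normal(size=(n_genes, 5)),
            index=[f"G{i}" for i in range(n_genes)],
            columns=["Basal", "Her2", "LumA", "LumB", "Normal"])
        return ref

    def test_identity_mapping_for_identical_centroids(self):
        ref = self._centroids(np.random.default_rng(8))
        clusters = ref.copy()
        clusters.columns = range(5)
        mapping = assign_subtype_labels(clusters, ref)
        assert [mapping[i] for i in range(5)] \
            == ["Basal", "Her2", "LumA", "LumB", "Normal"]

    def test_permutation_is_inverted(self):
        ref = self._centroids(np.random.default_rng(9))
        perm = [3, 0, 4, 1, 2]
        clusters = ref.iloc[:, perm].copy()
        clusters.columns = range(5)
        mapping = assign_subtype_labels(clusters, ref)
        assert [mapping[i] for i in range(5)] == list(ref.columns[perm])

    def test_tied_clusters_resolve_by_index_order(self):
        ref = self._centroids(np.random.default_rng(10))
        clusters = pd.DataFrame(
            {0: ref["Basal"], 1: ref["Basal"]}, index=ref.index)
        mapping = assign_subtype_labels(clusters, ref)
        assert mapping[0] == "Basal"    # first index wins the tie
        assert mapping[1] != "Basal"    # other cluster takes its next best

    def test_monotone_transform_invariance(self):
        """Spearman matching depends only on ranks: a common monotone
        transform of both centroid sets leaves the mapping unchanged."""
        rng = np.random.default_rng(11)
        ref = self._centroids(rng)
        clusters = (ref + rng.normal(0, 0.3, size=ref.shape)).iloc[:, [1, 2, 0]]
        clusters.columns = range(3)
        before = assign_subtype_labels(clusters, ref)
        after = assign_subtype_labels(clusters ** 3, ref ** 3)
        assert before == after

    def test_empty_cluster_set_is_rejected(self):
        ref = self._centroids(np.random.default_rng(12))
        with pytest.raises(StructuralError):
            assign_subtype_labels(ref.iloc[:, :0], ref)


class TestUnsupervisedCurve:
    def test_curve_runs_and_is_deterministic(self, small_cohort):
        config = CurveConfig(
            training_sizes=(80,), n_rounds=2,
            datasets=(("Panel", DatasetDef("informative_panel", panel_size=40)),),
            master_seed=60)
        a = run_unsupervised_curve(small_cohort, config, alpha=0.05, n_sim=30)
        b = run_unsupervised_curve(small_cohort, config, alpha=0.05, n_sim=30)
        pd.testing.assert_frame_equal(a.records, b.records)
        assert set(a.records.columns) >= {"n_clusters", "accuracy",
                                          "balanced_accuracy"}
        assert ((a.records["accuracy"] >= 0) & (a.records["accuracy"] <= 1)).all()
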