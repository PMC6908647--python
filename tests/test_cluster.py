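import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from methmarker.cluster import (ConsensusKMeans, cluster_association,
                                cluster_methylation_anova, consensus_cluster,
                                fisher_exact_rxc, label_shares, pac_score,
                                select_variable_probes)


def _blobs(rng, n_per=15, sep=5.0, d=4):
    X = np.vstack([rng.normal(0, 1, size=(n_per, d)),
                   rng.normal(sep, 1, size=(n_per, d))])
    truth = np.array([0] * n_per + [1] * n_per)
    return X, truth


class TestVariableProbes:
    def _frames(self, tumor_rows, normal_rows, regions, relations):
        probes = [f"cg{i}" for i in range(len(tumor_rows))]
        tumor = pd.DataFrame(tumor_rows, index=probes)
        normal = pd.DataFrame(normal_rows, index=probes)
        ann = pd.DataFrame({
            "chromosome": "chr1", "position": 1, "gene": "G1",
            "gene_region": regions, "cgi_relation": relations,
            "snp_flag": False}, index=pd.Index(probes, name="probe_id"))
        return tumor, normal, ann

    def test_sd_boundary_is_strict(self):
        # row engineered to an exact sample SD of 0.2
        row = [0.3, 0.3, 0.7, 0.7]
        assert np.std(row, ddof=1) == pytest.approx(0.23, abs=0.01)
        scaled = 0.5 + (np.array(row) - 0.5) * (0.2 / np.std(row, ddof=1))
        tumor, normal, ann = self._frames(
            [scaled], [[0.01] * 4], ["TSS200"], ["Island"])
        assert select_variable_probes(tumor, normal, ann) == []

    def test_open_sea_probe_excluded_despite_variance(self):
        tumor, normal, ann = self._frames(
            [[0.1, 0.9, 0.1, 0.9]], [[0.01] * 4], ["TSS200"], ["OpenSea"])
        assert select_variable_probes(tumor, normal, ann) == []

    def test_high_normal_mean_excluded(self):
        tumor, normal, ann = self._frames(
            [[0.1, 0.9, 0.1, 0.9]], [[0.5] * 4], ["TSS200"], ["Island"])
        assert select_variable_probes(tumor, normal, ann) == []

    def test_planted_cimp_block_selected(self, default_cohort):
        from methmarker.preprocess import filter_probes, impute_missing
        beta, ann, _counts, sheet, truth = default_cohort
        filtered, _ = filter_probes(beta, ann)
        imputed = impute_missing(filtered, sheet)
        tumors = list(truth.true_cluster_labels)
        normals = sheet.index[sheet["condition"] == "normal"]
        selected = select_variable_probes(imputed[tumors], imputed[normals],
                                          ann)
        cimp_block = [p for p in imputed.index
                      if ann.loc[p, "cgi_relation"] == "Island"
                      and imputed.loc[p, normals].mean() < 0.05
                      and imputed.loc[p, tumors].std(ddof=1) > 0.2]
        assert set(selected) == set(cimp_block)
        assert len(selected) >= 50  # most of the planted 60-probe block


class TestConsensusKMeans:
    def test_planted_partition_recovered(self, rng):
        X, truth = _blobs(rng)
        model = ConsensusKMeans(n_clusters=2, n_reps=60, random_state=0)
        labels = model.fit_predict(X)
        assert adjusted_rand_score(truth, labels) == 1.0
        c = model.consensus_matrix_
        assert np.allclose(c, c.T) and np.allclose(np.diag(c), 1.0)
        assert c.min() >= 0 and c.max() <= 1
        within = c[:15, :15][np.triu_indices(15, k=1)]
        between = c[:15, 15:]
        assert within.min() > 0.9 and between.max() < 0.1

    def test_k_larger_than_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            ConsensusKMeans(n_clusters=5).fit(rng.normal(size=(3, 2)))

    def test_two_samples_two_clusters_degenerate(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        model = ConsensusKMeans(n_clusters=2, n_reps=20,
                                subsample_frac=1.0, random_state=0).fit(X)
        assert model.labels_[0] != model.labels_[1]

    def test_full_subsampling_gives_binary_consensus(self, rng):
        X, _ = _blobs(rng, n_per=8)
        model = ConsensusKMeans(n_clusters=2, n_reps=25, subsample_frac=1.0,
                                random_state=1).fit(X)
        tri = model.consensus_matrix_[np.triu_indices(16, k=1)]
        assert set(np.round(tri, 6)) <= {0.0, 1.0}

    def test_same_seed_identical_consensus(self, rng):
        X, _ = _blobs(rng)
        a = ConsensusKMeans(n_clusters=2, n_reps=30, random_state=7).fit(X)
        b = ConsensusKMeans(n_clusters=2, n_reps=30, random_state=7).fit(X)
        assert np.array_equal(a.consensus_matrix_, b.consensus_matrix_)
        assert np.array_equal(a.labels_, b.labels_)

    def test_separation_increases_within_cluster_consensus(self, rng):
        pacs = []
        for sep in (0.5, 2.0, 6.0):
            X, truth = _blobs(rng, sep=sep)
            m = ConsensusKMeans(n_clusters=2, n_reps=40, random_state=3).fit(X)
            within = np.mean([m.consensus_matrix_[i, j]
                              for i in range(30) for j in range(30)
                              if i < j and truth[i] == truth[j]])
            pacs.append(within)
        assert pacs[0] < pacs[1] < pacs[2] or (pacs[1] > 0.99 and pacs[2] > 0.99)

    def test_pac_score_low_for_clean_partition(self, rng):
        X, _ = _blobs(rng, sep=8.0)
        m = ConsensusKMeans(n_clusters=2, n_reps=40, random_state=0).fit(X)
        assert pac_score(m.consensus_matrix_) < 0.05


class TestFisherExact:
    def test_diagonal_two_by_two(self):
        res = fisher_exact_rxc(np.array([[3, 0], [0, 3]]))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(4))
    def test_two_by_two_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 8, size=(2, 2)) + 1
        res = fisher_exact_rxc(table)
        expected = sps.fisher_exact(table).pvalue
        assert res.p_value == pytest.approx(expected)

    def test_monte_carlo_agrees_with_exact(self):
        table = np.array([[8, 3, 1], [2, 7, 2], [1, 2, 10]])  # total 36
        exact = fisher_exact_rxc(table, exact_max_total=100)
        mc = fisher_exact_rxc(table, exact_max_total=10, seed=5)
        assert exact.method == "exact" and mc.method == "monte-carlo"
        assert mc.p_value == pytest.approx(exact.p_value, abs=4 * (mc.se or 1e-3))

    def test_independent_feature_p_uniform(self, rng):
        """Exact Fisher p-values are stochastically >= uniform under
        independence (KS check on 300 simulated 2-cluster tables)."""
        ps = []
        for _ in range(300):
            labels = pd.Series(rng.integers(0, 2, size=24))
            feature = pd.Series(rng.integers(0, 2, size=24))
            ps.append(cluster_association(labels, feature).p_value)
        # discrete exact tests are conservative: P(p <= a) <= a
        for a in (0.05, 0.1, 0.25, 0.5):
            assert np.mean(np.array(ps) <= a) <= a + 0.05

    def test_constant_feature_gives_p_one(self):
        labels = pd.Series([0, 0, 1, 1])
        feature = pd.Series(["x", "x", "x", "x"])
        assert cluster_association(labels, feature).p_value == 1.0


class TestAnova:
    def test_identical_groups(self):
        labels = pd.Series([0, 0, 0, 1, 1, 1])
        means = pd.Series([1.0, 2, 3, 1, 2, 3])
        f, p = cluster_methylation_anova(labels, means)
        assert f == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_zero_within_variance(self):
        labels = pd.Series([0, 0, 0, 1, 1, 1])
        means = pd.Series([0.0, 0, 0, 1, 1, 1])
        f, p = cluster_methylation_anova(labels, means)
        assert f == np.inf and p < 1e-300

    def test_matches_sum_of_squares_oracle(self, rng):
        labels = pd.Series(rng.integers(0, 3, size=30))
        while labels.value_counts().min() < 2:
            labels = pd.Series(rng.integers(0, 3, size=30))
        means = pd.Series(rng.uniform(size=30))
        f, p = cluster_methylation_anova(labels, means)
        grand = means.mean()
        groups = [means[labels == c] for c in sorted(labels.unique())]
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b, df_w = len(groups) - 1, len(means) - len(groups)
        f_oracle = (ss_between / df_b) / (ss_within / df_w)
        assert f == pytest.approx(f_oracle)
        assert p == pytest.approx(sps.f.sf(f_oracle, df_b, df_w))

    def test_small_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_methylation_anova(pd.Series([0, 1, 1]),
                                      pd.Series([0.1, 0.2, 0.3]))


def test_consensus_cluster_recovers_planted_cimp(default_cohort):
    """Consensus K-means on the variable CGI-promoter block reproduces the
    planted three-cluster CIMP partition (ARI = 1) deterministically."""
    from methmarker.preprocess import filter_probes, impute_missing
    beta, ann, _counts, sheet, truth = default_cohort
    filtered, _ = filter_probes(beta, ann)
    imputed = impute_missing(filtered, sheet)
    tumors = list(truth.true_cluster_labels)
    normals = sheet.index[sheet["condition"] == "normal"]
    selected = select_variable_probes(imputed[tumors], imputed[normals], ann)
    result = consensus_cluster(imputed.loc[selected, tumors], k=3,
                               n_reps=100, seed=13)
    truth_labels = [truth.true_cluster_labels[s] for s in tumors]
    assert adjusted_rand_score(truth_labels, result.labels.to_numpy()) == 1.0
    again = consensus_cluster(imputed.loc[selected, tumors], k=3,
                              n_reps=100, seed=13)
    pd.testing.assert_frame_equal(result.consensus_matrix,
                                  again.consensus_matrix)
    shares = label_shares(result.labels)
    assert sum(shares.values()) == pytest.approx(1.0)
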