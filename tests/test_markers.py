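from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.model_selection import StratifiedKFold

from methmarker.evaluate import RidgeLogisticRegression
from methmarker.markers import (CandidateSet, InformationGainSelector,
                                build_candidates, ig_filter,
                                information_gain, sbfs, specificity_filter)


def ig_oracle(x, y, n_bins):
    """Brute-force mutual information from the joint bin/class counts."""
    bins = np.minimum((np.clip(np.asarray(x, float), 0, 1) * n_bins).astype(int),
                      n_bins - 1)
    classes = sorted(set(y))
    n = len(x)
    joint = {}
    for b, c in zip(bins, y):
        joint[(b, c)] = joint.get((b, c), 0) + 1
    mi = 0.0
    for (b, c), nbc in joint.items():
        pbc = nbc / n
        pb = sum(v for (bb, _), v in joint.items() if bb == b) / n
        pc = sum(v for (_, cc), v in joint.items() if cc == c) / n
        mi += pbc * np.log2(pbc / (pb * pc))
    return mi


class TestInformationGain:
    def test_constant_feature_has_zero_gain(self):
        y = np.array([0, 0, 1, 1])
        assert information_gain([0.5] * 4, y) == 0.0

    def test_perfect_separation_attains_class_entropy(self):
        x = [0.05, 0.05, 0.95, 0.95]
        y = np.array([0, 0, 1, 1])
        assert information_gain(x, y) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed,n_bins", [(0, 4), (1, 4), (2, 10)])
    def test_matches_joint_entropy_oracle(self, seed, n_bins):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=20)
        y = rng.integers(0, 2, size=20)
        while len(set(y)) < 2:
            y = rng.integers(0, 2, size=20)
        assert information_gain(x, y, n_bins=n_bins) == pytest.approx(
            ig_oracle(x, y, n_bins))

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_bounded_by_feature_and_class_entropy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        x = rng.uniform(size=n)
        y = np.array([0, 1] + list(rng.integers(0, 2, size=n - 2)))
        ig = information_gain(x, y)
        bins = np.minimum((x * 10).astype(int), 9)
        def h(v):
            _, c = np.unique(v, return_counts=True)
            p = c / c.sum()
            return -(p * np.log2(p)).sum()
        assert -1e-9 <= ig <= min(h(bins), h(y)) + 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            information_gain([0.1, 0.9], np.array([1, 1]))


class TestIGSelector:
    def test_threshold_is_strict_and_ranking_descending(self, rng):
        n = 200
        y = np.array(["a"] * 100 + ["b"] * 100)
        informative = np.where(y == "a", 0.1, 0.9) + rng.normal(0, 0.02, n)
        noise = rng.uniform(size=(n, 3))
        X = np.column_stack([informative, noise])
        sel = InformationGainSelector(threshold=0.3).fit(np.clip(X, 0, 1), y)
        assert sel.support_[0] and not sel.support_[1:].any()
        assert sel.ranking_[0] == 0
        assert np.all(np.diff(sel.gains_[sel.ranking_]) <= 1e-12)

    def test_shuffled_labels_rarely_pass(self, rng):
        """Uninformative probes: >=99% fail the 0.3-bit cutoff under
        label shuffling (null simulation, 300 probes)."""
        n = 200
        X = rng.uniform(size=(n, 300))
        y = rng.permutation(np.array([0] * 100 + [1] * 100))
        sel = InformationGainSelector(threshold=0.3).fit(X, y)
        assert sel.support_.mean() <= 0.01

    def test_planted_markers_all_pass(self, default_cohort):
        from methmarker.preprocess import impute_missing
        beta, _ann, _counts, sheet, truth = default_cohort
        target = sheet.index[sheet["cancer_type"] == "cervical"]
        imputed = impute_missing(beta[target], sheet.loc[target])
        y = sheet.loc[target, "condition"].to_numpy()
        for probe in truth.specific_marker_probe_ids:
            assert information_gain(imputed.loc[probe].to_numpy(), y) > 0.3


def _toy_candidates():
    prov = pd.DataFrame(
        {"gene": ["G1", "G2", "G3"], "delta": [0.4, 0.3, 0.5],
         "fdr": [1e-5] * 3},
        index=pd.Index(["cg0", "cg1", "cg2"], name="probe_id"))
    c = CandidateSet(provenance=prov)
    c.add_stage("initial", ["cg0", "cg1", "cg2"])
    return c


class TestCandidatesAndSpecificity:
    def _ann(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "gene_region", "cgi_relation"],
            index=pd.Index([f"cg{i}" for i in range(len(rows))],
                           name="probe_id"),
        ).assign(chromosome="chr1", position=1, snp_flag=False)

    def _dmcs(self, directions):
        return pd.DataFrame(
            {"delta": [0.4 if d == "hyper" else -0.4 for d in directions],
             "fdr": 1e-5, "direction": directions},
            index=[f"cg{i}" for i in range(len(directions))])

    def test_body_probe_of_hyper_down_gene_excluded(self):
        ann = self._ann([("G1", "Body", "Island")])
        c = build_candidates(self._dmcs(["hyper"]), {"G1"}, ann)
        assert c.probes("initial") == []

    def test_hypo_dmc_in_promoter_excluded(self):
        ann = self._ann([("G1", "TSS200", "Island")])
        c = build_candidates(self._dmcs(["hypo"]), {"G1"}, ann)
        assert c.probes("initial") == []

    def test_matches_join_oracle_on_cohort(self, default_cohort):
        from methmarker import io as mio
        from methmarker.dmc import call_dmcs, dmc_stats, map_dmcs_to_genes
        from methmarker.preprocess import filter_probes, impute_missing

        beta, ann, _counts, sheet, _truth = default_cohort
        cols = sheet.index[sheet["cancer_type"] == "cervical"]
        filtered, _ = filter_probes(beta[cols], ann)
        imputed = impute_missing(filtered, sheet.loc[cols])
        dmcs = call_dmcs(dmc_stats(imputed, sheet.loc[cols, "condition"]))
        dmg = map_dmcs_to_genes(dmcs, ann)
        hyper_down = set(list(dmg.hyper_genes)[:5])
        c = build_candidates(dmcs, hyper_down, ann)
        expected = set()
        hyper_probes = set(dmcs.index[dmcs["direction"] == "hyper"])
        for probe, gene, region in mio.iter_gene_links(ann):
            if (probe in hyper_probes and region in ("TSS1500", "TSS200")
                    and gene in hyper_down):
                expected.add(probe)
        assert set(c.probes("initial")) == expected

    def test_candidate_in_one_other_cancer_removed(self):
        c = _toy_candidates()
        other = {"other1": pd.DataFrame(index=["cg1"])}
        out = specificity_filter(c, other)
        assert out.probes("specificity_filtered") == ["cg0", "cg2"]

    def test_no_other_tables_is_identity(self):
        c = specificity_filter(_toy_candidates(), {})
        assert c.probes("specificity_filtered") == ["cg0", "cg1", "cg2"]

    def test_monotone_in_added_tables(self):
        base = specificity_filter(_toy_candidates(),
                                  {"a": pd.DataFrame(index=["cg0"])})
        more = specificity_filter(_toy_candidates(),
                                  {"a": pd.DataFrame(index=["cg0"]),
                                   "b": pd.DataFrame(index=["cg2"])})
        assert set(more.probes("specificity_filtered")) <= set(
            base.probes("specificity_filtered"))

    def test_stage_nesting_enforced(self):
        c = _toy_candidates()
        with pytest.raises(ValueError):
            c.add_stage("specificity_filtered", ["cg0", "cg9"])


class TestSBFS:
    def _beta(self, X, probes):
        return pd.DataFrame(np.asarray(X).T, index=probes,
                            columns=[f"s{j}" for j in range(len(X))])

    def test_single_candidate_returned(self, rng):
        y = np.array(["n"] * 10 + ["t"] * 10)
        x = np.where(y == "t", 0.9, 0.1) + rng.normal(0, 0.02, 20)
        beta = self._beta(np.clip(x[:, None], 0, 1), ["cg0"])
        panel = sbfs(["cg0"], beta, y, seed=0)
        assert panel.probe_ids == ["cg0"]

    def test_matches_exhaustive_subset_search(self, rng):
        """Greedy backward elimination finds the same best CV accuracy as
        exhaustive search over all 63 non-empty subsets (2 informative of 6)."""
        n = 40
        y = np.array(["normal"] * 20 + ["tumor"] * 20)
        f0 = np.where(y == "tumor", 0.85, 0.15) + rng.normal(0, 0.05, n)
        f1 = np.where(y == "tumor", 0.75, 0.25) + rng.normal(0, 0.05, n)
        noise = rng.uniform(size=(n, 4))
        X = np.clip(np.column_stack([f0, f1, noise]), 0, 1)
        probes = [f"cg{i}" for i in range(6)]
        beta = self._beta(X, probes)
        panel = sbfs(probes, beta, y, seed=3, cv=5)

        splits = list(StratifiedKFold(5, shuffle=True,
                                      random_state=3).split(X, y))

        def cv_acc(cols):
            correct = 0
            for train, test in splits:
                m = RidgeLogisticRegression().fit(X[np.ix_(train, cols)],
                                                  y[train])
                correct += int((m.predict(X[np.ix_(test, cols)])
                                == y[test]).sum())
            return correct / n

        best = max(cv_acc(list(c)) for r in range(1, 7)
                   for c in combinations(range(6), r))
        assert panel.cv_accuracy == pytest.approx(best)
        assert set(panel.probe_ids) <= {"cg0", "cg1"}

    def test_same_seed_same_trajectory(self, rng):
        n = 30
        y = np.array(["a"] * 15 + ["b"] * 15)
        X = np.clip(rng.uniform(size=(n, 4))
                    + 0.3 * (y == "b")[:, None], 0, 1)
        probes = [f"cg{i}" for i in range(4)]
        beta = self._beta(X, probes)
        p1 = sbfs(probes, beta, y, seed=5)
        p2 = sbfs(probes, beta, y, seed=5)
        assert p1.trajectory == p2.trajectory
        assert p1.probe_ids == p2.probe_ids

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            sbfs([], pd.DataFrame(), np.array(["a", "b"]))


def test_end_to_end_candidate_funnel(default_cohort):
    """Full funnel on the default cohort: candidates = specific + shared
    markers, screen keeps exactly the specific ones, IG keeps all of them,
    and SBFS returns a subset of the planted specific markers."""
    from methmarker.dmc import call_dmcs, dmc_stats, map_dmcs_to_genes
    from methmarker.preprocess import filter_probes, impute_missing

    beta, ann, _counts, sheet, truth = default_cohort
    filtered, _ = filter_probes(beta, ann)
    imputed = impute_missing(filtered, sheet)
    cond = sheet["condition"]
    target_t = sheet.index[(sheet["cancer_type"] == "cervical")
                           & (cond == "tumor")]
    normals = sheet.index[cond == "normal"]
    cols = target_t.union(normals, sort=False)
    dmcs = call_dmcs(dmc_stats(imputed[cols], cond.loc[cols]))
    dmg = map_dmcs_to_genes(dmcs, ann)
    marker_genes = {g for _p, g, _s in truth.coupling}
    hyper_down = set(dmg.hyper_genes) & marker_genes
    c = build_candidates(dmcs, hyper_down, ann)
    assert set(c.probes("initial")) == set(truth.specific_marker_probe_ids
                                           + truth.shared_marker_probe_ids)
    other = {}
    for ctype in ("other1", "other2"):
        ocols = sheet.index[sheet["cancer_type"] == ctype]
        other[ctype] = call_dmcs(dmc_stats(imputed[ocols], cond.loc[ocols]))
    c = specificity_filter(c, other)
    assert set(c.probes("specificity_filtered")) == set(
        truth.specific_marker_probe_ids)
    clf_cols = sheet.index[sheet["cancer_type"] == "cervical"]
    y = cond.loc[clf_cols].to_numpy()
    c, gains = ig_filter(c, imputed[clf_cols], y)
    assert set(c.probes("ig_filtered")) == set(truth.specific_marker_probe_ids)
    panel = sbfs(c, imputed[clf_cols], y, seed=1, gains=gains)
    assert set(panel.probe_ids) <= set(truth.specific_marker_probe_ids)
    assert not set(panel.probe_ids) & set(truth.shared_marker_probe_ids)
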