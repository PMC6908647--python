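"""CIMP subtype discovery by subsampled K-means consensus clustering.

Variable-probe selection follows the CIMP convention: CpG-island promoter
probes that are near-unmethylated in normals (mean beta below
``normal_mean_max``) but variable in tumors (SD above ``sd_min``).

``ConsensusKMeans`` is an sklearn-style clusterer: each of ``n_reps``
repetitions subsamples a fraction of the samples without replacement, runs
K-means (Euclidean, k-means++), and accumulates a co-clustering indicator;
``consensus(i, j)`` is the number of times i and j co-clustered divided by
the number of times both were sampled.  Final labels come from
average-linkage hierarchical clustering of ``1 - consensus`` cut at k.

Cluster-clinical association uses an r x c Fisher exact test (full network
enumeration for small tables, Patefield Monte-Carlo sampling otherwise), and
cluster methylation differences use one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.utils.validation import check_array

from . import io as mio

__all__ = [
    "select_variable_probes", "ConsensusKMeans", "consensus_cluster",
    "cluster_association", "cluster_methylation_anova", "label_shares",
    "FisherResult", "pac_score",
]


def select_variable_probes(
    beta_tumor: pd.DataFrame,
    beta_normal: pd.DataFrame,
    ann: pd.DataFrame,
    sd_min: float = 0.2,
    normal_mean_max: float = 0.05,
    restrict_cgi_promoter: bool = True,
    promoter_regions: tuple[str, ...] = mio.PROMOTER_REGIONS,
) -> list[str]:
    """Probes with tumor SD > sd_min and normal mean < normal_mean_max.

    With ``restrict_cgi_promoter`` the probe must also lie in a CpG island
    and link to at least one gene through a promoter-class region.
    """
    common = beta_tumor.index
    sd = beta_tumor.std(axis=1, ddof=1)
    mean_normal = beta_normal.loc[common].mean(axis=1)
    keep = (sd > sd_min) & (mean_normal < normal_mean_max)
    if restrict_cgi_promoter:
        sub = ann.loc[common]
        promoter_probes = {
            probe for probe, _gene, region in mio.iter_gene_links(sub)
            if region in promoter_regions
        }
        is_cgi = sub["cgi_relation"] == "Island"
        keep &= is_cgi & common.isin(promoter_probes)
    return list(common[keep])


class ConsensusKMeans(ClusterMixin, BaseEstimator):
    """Consensus clustering over subsampled K-means runs.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k (>= 2).
    n_reps : int
        Subsampling repetitions.
    subsample_frac : float
        Fraction of samples drawn (without replacement) per repetition.
    n_init : int
        k-means++ restarts per repetition.
    random_state : int
        Seed; fixed seed gives an identical consensus matrix.

    Attributes
    ----------
    consensus_matrix_ : ndarray (n_samples, n_samples)
        Symmetric, unit diagonal, entries in [0, 1].
    labels_ : ndarray (n_samples,)
    """

    def __init__(self, n_clusters: int = 3, n_reps: int = 1000,
                 subsample_frac: float = 0.8, n_init: int = 10,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_reps = n_reps
        self.subsample_frac = subsample_frac
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        n = X.shape[0]
        k = self.n_clusters
        if k < 2:
            raise ValueError("n_clusters must be >= 2")
        if n < k:
            raise ValueError(f"need at least n_clusters={k} samples, got {n}")
        rng = np.random.default_rng(self.random_state)
        m = max(k, int(np.ceil(self.subsample_frac * n)))
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for _ in range(self.n_reps):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            rep_seed = int(rng.integers(0, 2**31 - 1))
            km = KMeans(n_clusters=k, n_init=self.n_init, random_state=rep_seed)
            labels = km.fit_predict(X[idx])
            sampled[np.ix_(idx, idx)] += 1
            for c in range(k):
                members = idx[labels == c]
                together[np.ix_(members, members)] += 1
        off_diag = ~np.eye(n, dtype=bool)
        if np.any(sampled[off_diag] == 0):
            raise RuntimeError(
                "some sample pairs were never co-subsampled; increase n_reps"
            )
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0
        self.consensus_matrix_ = consensus
        hc = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                     linkage="average")
        self.labels_ = hc.fit_predict(1.0 - consensus)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ConsensusResult:
    selected_probe_ids: list[str]
    consensus_matrix: pd.DataFrame
    labels: pd.Series
    cluster_mean_methylation: pd.Series


def consensus_cluster(
    beta_subset: pd.DataFrame,
    k: int,
    n_reps: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
) -> ConsensusResult:
    """Cluster samples (columns of *beta_subset*) on the selected probes."""
    model = ConsensusKMeans(n_clusters=k, n_reps=n_reps,
                            subsample_frac=subsample_frac, n_init=n_init,
                            random_state=seed)
    X = beta_subset.to_numpy(dtype=float).T  # samples x probes
    model.fit(X)
    labels = pd.Series(model.labels_, index=beta_subset.columns, name="cluster")
    per_sample_mean = beta_subset.mean(axis=0)
    cluster_means = per_sample_mean.groupby(labels).mean()
    consensus = pd.DataFrame(model.consensus_matrix_,
                             index=beta_subset.columns,
                             columns=beta_subset.columns)
    return ConsensusResult(list(beta_subset.index), consensus, labels,
                           cluster_means)


def pac_score(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: consensus entries in (lower, upper)."""
    c = np.asarray(consensus)
    tri = c[np.triu_indices_from(c, k=1)]
    return float(np.mean((tri > lower) & (tri < upper)))


# ---------------------------------------------------------------------------
# Fisher exact test on r x c tables


@dataclass
class FisherResult:
    p_value: float
    method: str                  # "exact" or "monte-carlo"
    se: float | None = None      # standard error of the Monte-Carlo estimate


def _table_log_prob(table: np.ndarray) -> float:
    """log multivariate hypergeometric probability of a table given margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        special.gammaln(rows + 1).sum() + special.gammaln(cols + 1).sum()
        - special.gammaln(n + 1) - special.gammaln(table + 1).sum()
    )


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield every non-negative integer table with the given margins."""
    r, c = len(rows), len(cols)
    table = np.zeros((r, c), dtype=np.int64)

    def fill(i: int, remaining_cols: np.ndarray):
        if i == r - 1:
            table[i] = remaining_cols
            yield table
            return
        def fill_row(j: int, left: int, rem: np.ndarray):
            if j == c - 1:
                if left <= rem[j]:
                    table[i, j] = left
                    yield rem - table[i]
                return
            for v in range(min(left, rem[j]) + 1):
                table[i, j] = v
                yield from fill_row(j + 1, left - v, rem)
        for new_rem in fill_row(0, int(rows[i]), remaining_cols):
            yield from fill(i + 1, new_rem.copy())

    yield from fill(0, cols.astype(np.int64))


def fisher_exact_rxc(
    table: np.ndarray,
    exact_max_total: int = 30,
    n_mc: int = 100_000,
    seed: int = 0,
) -> FisherResult:
    """Two-sided Fisher exact test on an r x c contingency table.

    Exact (sum of probabilities of tables at least as extreme, i.e. with
    probability <= that of the observed table) when the table is at most
    2 x 3 in either orientation or the total is <= ``exact_max_total``;
    otherwise a Monte-Carlo estimate over ``n_mc`` Patefield-sampled tables.
    """
    table = np.asarray(table, dtype=np.int64)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if min(table.shape) < 2 or np.any(rows == 0) or np.any(cols == 0):
        # degenerate margins carry no information
        return FisherResult(1.0, "exact")
    total = int(table.sum())
    log_p_obs = _table_log_prob(table)
    tol = 1e-9
    small = sorted(table.shape) <= [2, 3] or total <= exact_max_total
    if small:
        p = 0.0
        for t in _enumerate_tables(rows, cols):
            lp = _table_log_prob(t)
            if lp <= log_p_obs + tol:
                p += np.exp(lp)
        return FisherResult(min(float(p), 1.0), "exact")
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(rows, cols)
    draws = sampler.rvs(n_mc, random_state=rng)
    lp = (special.gammaln(rows + 1).sum() + special.gammaln(cols + 1).sum()
          - special.gammaln(total + 1)
          - special.gammaln(draws + 1).sum(axis=(1, 2)))
    hits = int(np.sum(lp <= log_p_obs + tol))
    p = hits / n_mc
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_mc))
    return FisherResult(float(p), "monte-carlo", se)


def cluster_association(
    labels: pd.Series,
    clinical_feature: pd.Series,
    seed: int = 0,
) -> FisherResult:
    """Fisher exact association between cluster labels and a categorical feature.

    Samples with a missing feature value are dropped; a single-level feature
    returns p = 1.
    """
    df = pd.DataFrame({"cluster": labels, "feature": clinical_feature}).dropna()
    if df["feature"].nunique() < 2 or df["cluster"].nunique() < 2:
        return FisherResult(1.0, "exact")
    table = pd.crosstab(df["cluster"], df["feature"]).to_numpy()
    return fisher_exact_rxc(table, seed=seed)


def cluster_methylation_anova(
    labels: pd.Series,
    sample_means: pd.Series,
) -> tuple[float, float]:
    """One-way ANOVA of per-sample mean methylation across clusters."""
    groups = [sample_means.loc[labels.index[labels == c]].to_numpy()
              for c in sorted(labels.unique())]
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every cluster needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # zero within-group variance
        return float("inf"), float(np.finfo(float).tiny)
    if np.isnan(p):
        return float(f), 1.0
    return float(f), float(max(p, np.finfo(float).tiny))


def label_shares(labels) -> dict:
    """Fraction of samples per label value (e.g. CIMP cluster or HPV status)."""
    s = pd.Series(list(labels))
    counts = s.value_counts()
    total = int(counts.sum())
    return {str(k): int(v) / total for k, v in counts.items()}
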