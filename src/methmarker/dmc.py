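"""Differential methylation: per-probe Wilcoxon tests, BH adjustment,
DMC calling, gene mapping, and genomic-context summaries.

A CpG is called differentially methylated when the tumor-normal mean beta
difference exceeds ``delta_threshold`` in absolute value (strictly) and the
Benjamini-Hochberg FDR is below ``fdr_threshold``.  Direction is the sign of
the difference: hyper (delta > 0) or hypo (delta < 0).

The rank-sum test is exact (full enumeration of rank splits) when both
groups have at most ``exact_max`` samples, and otherwise uses the
tie-corrected normal approximation with midranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import io as mio

__all__ = [
    "wilcoxon_dmc", "bh_adjust", "call_dmcs", "map_dmcs_to_genes",
    "context_summary", "DMGSet",
]

EXACT_MAX = 8


def _exact_rank_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of C(n1+n2, n1) splits.

    Ties are handled through midranks: the null distribution of the rank sum
    is taken over all equally likely assignments of the observed (mid)ranks
    to the first group.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    expected = n1 * (n1 + n2 + 1) / 2.0
    d_obs = abs(w_obs - expected)
    n_total = n1 + n2
    hits = 0
    for idx in combinations(range(n_total), n1):
        w = ranks[list(idx)].sum()
        if abs(w - expected) >= d_obs - 1e-12:
            hits += 1
    return hits / comb(n_total, n1)


def wilcoxon_dmc(
    beta: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    exact_max: int = EXACT_MAX,
) -> pd.DataFrame:
    """Per-probe two-sided rank-sum test of tumor vs normal beta values.

    Parameters
    ----------
    beta
        Imputed beta matrix (no missing values), probes x samples.
    groups
        Per-sample condition labels aligned with ``beta.columns``
        ("tumor"/"normal") or a boolean array (True = tumor).

    Returns a DataFrame indexed by probe with columns ``statistic`` (rank-sum
    of the tumor group) and ``p_value``.
    """
    if isinstance(groups, pd.Series):
        groups = groups.loc[beta.columns]
    g = np.asarray(groups)
    tumor = g if g.dtype == bool else (g == "tumor")
    n1, n2 = int(tumor.sum()), int((~tumor).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    values = beta.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("beta matrix contains missing values; impute first")

    xs = values[:, tumor]
    ys = values[:, ~tumor]
    ranks = stats.rankdata(values, axis=1)
    statistic = ranks[:, tumor].sum(axis=1)

    if n1 <= exact_max and n2 <= exact_max:
        p = np.array([_exact_rank_p(xs[i], ys[i]) for i in range(len(beta))])
    else:
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(xs, ys, axis=1, alternative="two-sided",
                                     method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
        # constant rows: zero rank variance, no evidence either way
        constant = np.ptp(values, axis=1) == 0
        p[constant] = 1.0
        p = np.nan_to_num(p, nan=1.0)
    return pd.DataFrame({"statistic": statistic, "p_value": p}, index=beta.index)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dmc_stats(
    beta: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    exact_max: int = EXACT_MAX,
) -> pd.DataFrame:
    """Full per-probe table: group means, delta, p, FDR."""
    if isinstance(groups, pd.Series):
        groups = groups.loc[beta.columns]
    g = np.asarray(groups)
    tumor = g if g.dtype == bool else (g == "tumor")
    test = wilcoxon_dmc(beta, groups, exact_max=exact_max)
    values = beta.to_numpy(dtype=float)
    mean_t = values[:, tumor].mean(axis=1)
    mean_n = values[:, ~tumor].mean(axis=1)
    out = pd.DataFrame(
        {
            "mean_beta_tumor": mean_t,
            "mean_beta_normal": mean_n,
            "delta": mean_t - mean_n,
            "p_value": test["p_value"],
        },
        index=beta.index,
    )
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out


def call_dmcs(
    stats_table: pd.DataFrame,
    delta_threshold: float = 0.2,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Select DMCs: |delta| strictly > delta_threshold and FDR < fdr_threshold."""
    keep = (stats_table["delta"].abs() > delta_threshold) & (
        stats_table["fdr"] < fdr_threshold
    )
    out = stats_table.loc[keep].copy()
    out["direction"] = np.where(out["delta"] > 0, "hyper", "hypo")
    return out


@dataclass
class DMGSet:
    """Differentially methylated genes via promoter DMCs.

    A gene is hypermethylated if at least one hyper DMC lies in one of its
    promoter-class probe links (and analogously hypomethylated); a gene with
    promoter DMCs of both directions appears in both maps.
    """

    hyper_genes: dict[str, list[str]] = field(default_factory=dict)  # gene -> probes
    hypo_genes: dict[str, list[str]] = field(default_factory=dict)


def map_dmcs_to_genes(
    dmcs: pd.DataFrame,
    ann: pd.DataFrame,
    promoter_regions: tuple[str, ...] = mio.PROMOTER_REGIONS,
) -> DMGSet:
    """Map promoter DMCs to genes, keeping supporting probes per gene."""
    missing = dmcs.index.difference(ann.index)
    if len(missing):
        raise KeyError(f"DMC probe(s) missing from annotation: {list(missing[:5])}")
    direction = dmcs["direction"]
    result = DMGSet()
    sub = ann.loc[ann.index.intersection(dmcs.index)]
    for probe, gene, region in mio.iter_gene_links(sub):
        if region not in promoter_regions:
            continue
        target = result.hyper_genes if direction[probe] == "hyper" else result.hypo_genes
        target.setdefault(gene, []).append(probe)
    return result


def _fractions(n_hyper: int, n_hypo: int) -> dict:
    total = n_hyper + n_hypo
    return {
        "hyper": n_hyper,
        "hypo": n_hypo,
        "total": total,
        "frac_hyper": n_hyper / total if total else 0.0,
        "frac_hypo": n_hypo / total if total else 0.0,
    }


def context_summary(
    dmcs: pd.DataFrame,
    ann: pd.DataFrame,
    promoter_regions: tuple[str, ...] = mio.PROMOTER_REGIONS,
) -> dict:
    """Hyper/hypo DMC counts and fractions per genomic context.

    Returns a dict with three blocks: ``location`` (all / promoter / CGI /
    CGI-promoter), ``cgi_relation`` (per relation class) and ``gene_region``
    (per region class; a DMC with links to several regions counts once per
    region class it touches).
    """
    if len(dmcs) == 0:
        empty = _fractions(0, 0)
        return {
            "location": {k: dict(empty) for k in
                         ("all", "promoter", "CGI", "CGI_promoter")},
            "cgi_relation": {k: dict(empty) for k in mio.CGI_RELATIONS},
            "gene_region": {k: dict(empty) for k in mio.GENE_REGIONS},
        }
    sub = ann.loc[dmcs.index]
    hyper = (dmcs["direction"] == "hyper").to_numpy()
    in_cgi = (sub["cgi_relation"] == "Island").to_numpy()
    probe_regions: dict[str, set[str]] = {p: set() for p in dmcs.index}
    for probe, _gene, region in mio.iter_gene_links(sub):
        probe_regions[probe].add(region)
    in_promoter = np.array(
        [bool(probe_regions[p] & set(promoter_regions)) for p in dmcs.index]
    )

    def block(mask: np.ndarray) -> dict:
        return _fractions(int((hyper & mask).sum()), int((~hyper & mask).sum()))

    every = np.ones(len(dmcs), dtype=bool)
    summary = {
        "location": {
            "all": block(every),
            "promoter": block(in_promoter),
            "CGI": block(in_cgi),
            "CGI_promoter": block(in_cgi & in_promoter),
        },
        "cgi_relation": {
            rel: block((sub["cgi_relation"] == rel).to_numpy())
            for rel in mio.CGI_RELATIONS
        },
        "gene_region": {
            region: block(np.array([region in probe_regions[p] for p in dmcs.index]))
            for region in mio.GENE_REGIONS
        },
    }
    return summary
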