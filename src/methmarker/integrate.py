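"""Methylation-expression integration.

* quadrant classification of genes: promoter methylation direction (hyper /
  hypo) crossed with expression direction (up / down);
* local correlation: Pearson r between each promoter CpG and the expression
  of its own gene; genes are classified positive / negative / both from the
  signs of their significant pairs;
* distant correlation: Pearson r between promoter CpGs of differentially
  methylated-and-expressed genes and the expression of all DEGs, excluding
  each CpG's own gene, summarized by the sign balance within hyper- and
  hypo-methylated source genes;
* a hypergeometric gene-set enrichment utility (GMT collections).

Expression values for correlation are log2(CPM + 1) with TMM-scaled library
sizes.  Significance means |r| above ``r_threshold`` with BH FDR below
``fdr_threshold``; BH is applied within each call, never pooled across the
local and distant analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io as mio
from .dmc import DMGSet, bh_adjust

__all__ = [
    "QuadrantSets", "quadrant_classify", "log_cpm",
    "local_correlation", "distant_correlation", "geneset_enrichment",
]


@dataclass
class QuadrantSets:
    hyper_up: set[str] = field(default_factory=set)
    hyper_down: set[str] = field(default_factory=set)
    hypo_up: set[str] = field(default_factory=set)
    hypo_down: set[str] = field(default_factory=set)


def quadrant_classify(dmg: DMGSet, deg_up: set[str], deg_down: set[str]) -> QuadrantSets:
    """Intersect promoter-methylation gene direction with expression direction."""
    hyper = set(dmg.hyper_genes)
    hypo = set(dmg.hypo_genes)
    return QuadrantSets(
        hyper_up=hyper & deg_up,
        hyper_down=hyper & deg_down,
        hypo_up=hypo & deg_up,
        hypo_down=hypo & deg_down,
    )


def log_cpm(counts: pd.DataFrame, factors: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) on TMM-effective library sizes."""
    eff = (factors.loc[counts.columns, "library_size"]
           * factors.loc[counts.columns, "factor"]).to_numpy(dtype=float)
    cpm = counts.to_numpy(dtype=float) / eff[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index,
                        columns=counts.columns)


def _pearson_with_p(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of one vector against rows of Y (vectorized)."""
    n = len(x)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


@dataclass
class CorrelationReport:
    records: pd.DataFrame              # probe_id, gene_id, r, p_value, fdr, mode, significant
    gene_classes: dict[str, str]       # gene -> positive / negative / both
    n_skipped_constant: int = 0
    n_skipped_few_samples: int = 0


def _correlate_pairs(
    pairs: list[tuple[str, str]],
    beta: pd.DataFrame,
    expr: pd.DataFrame,
    mode: str,
    r_threshold: float,
    fdr_threshold: float,
    min_samples: int = 3,
) -> CorrelationReport:
    shared = beta.columns.intersection(expr.columns)
    n_skip_few = 0
    n_skip_const = 0
    if len(shared) < min_samples:
        return CorrelationReport(
            pd.DataFrame(columns=["probe_id", "gene_id", "r", "p_value",
                                  "fdr", "mode", "significant"]),
            {}, 0, len(pairs))
    b = beta[shared]
    e = expr[shared]
    rows = []
    # group pairs by probe so each probe's vector is correlated against a block
    by_probe: dict[str, list[str]] = {}
    for probe, gene in pairs:
        by_probe.setdefault(probe, []).append(gene)
    for probe, genes in by_probe.items():
        x = b.loc[probe].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            n_skip_const += len(genes)
            continue
        Y = e.loc[genes].to_numpy(dtype=float)
        const_y = np.ptp(Y, axis=1) == 0
        r, p = _pearson_with_p(x, Y)
        for gi, gene in enumerate(genes):
            if const_y[gi]:
                n_skip_const += 1
                continue
            rows.append((probe, gene, r[gi], p[gi]))
    records = pd.DataFrame(rows, columns=["probe_id", "gene_id", "r", "p_value"])
    if len(records):
        records["fdr"] = bh_adjust(records["p_value"].to_numpy())
        records["mode"] = mode
        records["significant"] = (records["r"].abs() > r_threshold) & (
            records["fdr"] < fdr_threshold
        )
    else:
        records["fdr"] = []
        records["mode"] = []
        records["significant"] = []

    gene_classes: dict[str, str] = {}
    sig = records[records["significant"]] if len(records) else records
    for gene, grp in sig.groupby("gene_id") if len(sig) else []:
        pos = (grp["r"] > 0).any()
        neg = (grp["r"] < 0).any()
        gene_classes[gene] = "both" if (pos and neg) else ("positive" if pos else "negative")
    return CorrelationReport(records, gene_classes, n_skip_const, n_skip_few)


def local_correlation(
    beta: pd.DataFrame,
    expr: pd.DataFrame,
    ann: pd.DataFrame,
    r_threshold: float = 0.3,
    fdr_threshold: float = 0.05,
    promoter_regions: tuple[str, ...] = mio.PROMOTER_REGIONS,
) -> CorrelationReport:
    """Correlate each promoter CpG with the expression of its own gene."""
    pairs = [
        (probe, gene)
        for probe, gene, region in mio.iter_gene_links(ann.loc[ann.index.intersection(beta.index)])
        if region in promoter_regions and gene in expr.index
    ]
    return _correlate_pairs(pairs, beta, expr, "local", r_threshold, fdr_threshold)


def distant_correlation(
    beta: pd.DataFrame,
    expr: pd.DataFrame,
    ann: pd.DataFrame,
    cpg_source_genes: dict[str, str],
    source_direction: dict[str, str],
    deg_genes: set[str],
    r_threshold: float = 0.3,
    fdr_threshold: float = 0.05,
) -> tuple[CorrelationReport, dict]:
    """Correlate source CpGs against all DEGs except each CpG's own gene.

    ``cpg_source_genes`` maps each tested CpG to its own (source) gene, which
    is excluded from that CpG's pairs; ``source_direction`` gives the
    methylation direction (hyper/hypo) of the source gene.  Returns the
    record report plus a summary of significant-pair sign fractions per
    source direction.
    """
    pairs = [
        (probe, gene)
        for probe in cpg_source_genes
        if probe in beta.index
        for gene in sorted(deg_genes)
        if gene in expr.index and gene != cpg_source_genes[probe]
    ]
    report = _correlate_pairs(pairs, beta, expr, "distant",
                              r_threshold, fdr_threshold)
    summary: dict[str, dict] = {}
    rec = report.records
    for direction in ("hyper", "hypo"):
        probes = {p for p, d in source_direction.items() if d == direction}
        sub = rec[rec["significant"] & rec["probe_id"].isin(probes)] if len(rec) else rec
        n_sig = len(sub)
        n_neg = int((sub["r"] < 0).sum()) if n_sig else 0
        summary[direction] = {
            "n_significant": n_sig,
            "frac_negative": n_neg / n_sig if n_sig else 0.0,
            "frac_positive": (n_sig - n_neg) / n_sig if n_sig else 0.0,
        }
    return report, summary


def geneset_enrichment(
    query_genes: set[str],
    universe: set[str],
    gmt_collections: dict[str, set[str]],
    top_n: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of *query_genes* in each gene set.

    Upper-tail p for an overlap at least as large as observed, BH-adjusted
    across sets, sorted by ascending p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(query_genes) <= set(universe):
        raise ValueError("query genes must be a subset of the universe")
    N = len(universe)
    n = len(query_genes)
    rows = []
    for name, genes in gmt_collections.items():
        in_universe = set(genes) & set(universe)
        K = len(in_universe)
        k = len(in_universe & set(query_genes))
        p = stats.hypergeom.sf(k - 1, N, K, n) if K else 1.0
        expected = n * K / N if N else 0.0
        fold = (k / expected) if expected > 0 else np.nan
        rows.append((name, k, K, fold, min(float(p), 1.0)))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "fold", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    out = out.sort_values(["p_value", "set"]).reset_index(drop=True)
    return out.head(top_n) if top_n else out
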