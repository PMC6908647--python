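"""Synthetic multi-cancer methylation + expression cohorts with known ground truth.

The generator emulates the data regimes of a 450K + RNA-seq tumor/normal study
across several cancer types:

* beta values are bounded, bimodal and heteroskedastic: each probe/sample value
  is drawn from Beta(mu*kappa, (1-mu)*kappa) around a state-dependent mean
  (normal-low baselines near 0.05-0.15, tumor-hypermethylated states shifted
  upward by ``hyper_delta``);
* planted *specific* markers are hypermethylated only in the target cancer's
  tumors; planted *shared* markers are hypermethylated in every simulated
  cancer type, so a cross-cancer specificity screen has real work to do;
* a designated block of CpG-island promoter probes carries a CIMP-like
  three-cluster structure (distinct mean offsets per tumor cluster) with
  near-zero methylation in normals;
* RNA-seq counts are negative binomial; genes coupled to a promoter CpG have
  their log-mean shifted by ``coupling_strength * (beta - mean beta)``, which
  produces the negative methylation-expression correlations the integration
  stage looks for;
* values go missing completely at random at ``missing_rate``.

Identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as mio

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "inject_missing"]


@dataclass
class CohortConfig:
    """Parameters of the simulated multi-cancer cohort.

    Defaults are the study conditions used throughout the test-suite: three
    cancer types with 100 tumors / 100 normals each, 2000 probes, 300 genes,
    4 target-specific and 6 shared hypermethylation markers with a mean beta
    shift of 0.4.
    """

    n_cancer_types: int = 3
    n_tumors: int = 100          # per cancer type
    n_normals: int = 100         # per cancer type
    n_probes: int = 2000
    n_genes: int = 300
    n_specific_markers: int = 4
    n_shared_markers: int = 6
    hyper_delta: float = 0.4     # tumor-normal mean beta shift at planted markers
    beta_precision: float = 50.0  # kappa of the Beta noise
    coupling_strength: float = -3.0  # d log(mean count) / d beta for coupled pairs
    nb_dispersion: float = 0.1
    missing_rate: float = 0.02
    n_cimp_clusters: int = 3
    seed: int = 0
    # background structure
    n_cimp_probes: int = 60
    n_hyper_background: int = 40  # hyper DMCs in gene bodies, all cancer types
    n_hypo_background: int = 40   # hypo DMCs in gene bodies, all cancer types
    n_direct_de: int = 30         # genes DE independently of methylation
    direct_de_log2fc: float = 3.0
    n_trans_targets: int = 0      # extra genes driven by the first specific marker
    snp_fraction: float = 0.02
    chrx_fraction: float = 0.02
    target_type: str = "cervical"

    def validate(self) -> None:
        counts = dict(n_cancer_types=self.n_cancer_types, n_tumors=self.n_tumors,
                      n_normals=self.n_normals, n_probes=self.n_probes,
                      n_genes=self.n_genes)
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_cancer_types < 2:
            raise ValueError("need at least 2 cancer types")
        if not 0 < self.hyper_delta < 1:
            raise ValueError("hyper_delta must lie in (0, 1)")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        n_special = (self.n_specific_markers + self.n_shared_markers
                     + self.n_cimp_probes + self.n_hyper_background
                     + self.n_hypo_background)
        if self.n_specific_markers + self.n_shared_markers > self.n_probes:
            raise ValueError("more planted markers than probes")
        if n_special > self.n_probes:
            raise ValueError("planted structure exceeds n_probes")
        n_coupled = self.n_specific_markers + self.n_shared_markers
        if n_coupled + self.n_direct_de + self.n_trans_targets > self.n_genes:
            raise ValueError("planted gene structure exceeds n_genes")


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery downstream."""

    specific_marker_probe_ids: list[str]
    shared_marker_probe_ids: list[str]
    true_deg_ids: dict[str, float]          # gene -> signed log2 effect in target tumors
    true_cluster_labels: dict[str, int]     # target tumor sample -> CIMP cluster
    coupling: list[tuple[str, str, int]]    # (probe, gene, sign of coupling)
    hyper_background_ids: list[str] = field(default_factory=list)
    hypo_background_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.specific_marker_probe_ids) & set(self.shared_marker_probe_ids)
        if overlap:
            raise ValueError(f"marker id sets must be disjoint, both contain {overlap}")

    def to_json(self, path) -> None:
        mio.write_json(asdict(self), path)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = mio.read_json(path)
        d["coupling"] = [tuple(t) for t in d["coupling"]]
        return cls(**d)


def _beta_noise(rng: np.random.Generator, mu: np.ndarray, kappa: float) -> np.ndarray:
    mu = np.clip(mu, 0.01, 0.99)
    return rng.beta(mu * kappa, (1.0 - mu) * kappa)


def generate_cohort(config: CohortConfig):
    """Simulate one cohort.

    Returns ``(beta, annotation, counts, sample_sheet, truth)`` where the
    first four are the standard pandas containers of :mod:`methmarker.io`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_types = config.n_cancer_types
    types = [config.target_type] + [f"other{i}" for i in range(1, n_types)]

    # ---- samples -----------------------------------------------------------
    sample_rows = []
    for t in types:
        for i in range(config.n_tumors):
            sample_rows.append((f"{t}_T{i:03d}", "tumor", t))
        for i in range(config.n_normals):
            sample_rows.append((f"{t}_N{i:03d}", "normal", t))
    sheet = pd.DataFrame(sample_rows, columns=["sample_id", "condition", "cancer_type"])
    sheet = sheet.set_index("sample_id")
    n_samples = len(sheet)
    is_tumor = (sheet["condition"] == "tumor").to_numpy()
    type_of = sheet["cancer_type"].to_numpy()
    target_tumor_mask = is_tumor & (type_of == config.target_type)
    target_tumors = sheet.index[target_tumor_mask].tolist()

    # ---- probe layout ------------------------------------------------------
    probes = [f"cg{i:06d}" for i in range(config.n_probes)]
    ns, nsh = config.n_specific_markers, config.n_shared_markers
    idx_specific = np.arange(0, ns)
    idx_shared = np.arange(ns, ns + nsh)
    off = ns + nsh
    idx_cimp = np.arange(off, off + config.n_cimp_probes)
    off += config.n_cimp_probes
    idx_hyper_bg = np.arange(off, off + config.n_hyper_background)
    off += config.n_hyper_background
    idx_hypo_bg = np.arange(off, off + config.n_hypo_background)
    off += config.n_hypo_background
    idx_null = np.arange(off, config.n_probes)

    # ---- genes -------------------------------------------------------------
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    # coupled genes: one per planted marker, in order
    idx_marker_genes = np.arange(0, ns + nsh)
    idx_direct_de = np.arange(ns + nsh, ns + nsh + config.n_direct_de)
    idx_trans = np.arange(ns + nsh + config.n_direct_de,
                          ns + nsh + config.n_direct_de + config.n_trans_targets)

    # ---- annotation --------------------------------------------------------
    chromosome = np.array([f"chr{(i % 22) + 1}" for i in range(config.n_probes)],
                          dtype=object)
    position = np.arange(1, config.n_probes + 1) * 1000
    gene_col = np.full(config.n_probes, "", dtype=object)
    region_col = np.full(config.n_probes, "", dtype=object)
    cgi_col = np.full(config.n_probes, "OpenSea", dtype=object)
    snp_col = np.zeros(config.n_probes, dtype=bool)

    for k, p in enumerate(np.concatenate([idx_specific, idx_shared])):
        gene_col[p] = genes[idx_marker_genes[k]]
        region_col[p] = "TSS200" if k % 2 == 0 else "TSS1500"
        cgi_col[p] = "Island"
    for k, p in enumerate(idx_cimp):
        # CIMP probes sit in CGI promoters of otherwise unremarkable genes
        g = config.n_genes - 1 - (k % max(1, config.n_genes - off))
        gene_col[p] = genes[g]
        region_col[p] = "TSS200" if k % 2 == 0 else "TSS1500"
        cgi_col[p] = "Island"
    body_regions = ["Body", "3UTR", "5UTR", "1stExon"]
    shelves = ["N_Shelf", "S_Shelf", "N_Shore", "S_Shore", "OpenSea"]
    for k, p in enumerate(np.concatenate([idx_hyper_bg, idx_hypo_bg])):
        gene_col[p] = genes[int(rng.integers(0, config.n_genes))]
        region_col[p] = body_regions[k % len(body_regions)]
        cgi_col[p] = shelves[k % len(shelves)]
    # null probes: random annotation, some with genes
    for p in idx_null:
        if rng.random() < 0.5:
            gene_col[p] = genes[int(rng.integers(0, config.n_genes))]
            region_col[p] = mio.GENE_REGIONS[int(rng.integers(0, 6))]
        cgi_col[p] = mio.CGI_RELATIONS[int(rng.integers(0, 6))]
    # QC fodder: SNP and chrX flags on null probes only
    n_snp = int(round(config.snp_fraction * config.n_probes))
    n_chrx = int(round(config.chrx_fraction * config.n_probes))
    qc_pool = rng.permutation(idx_null)
    snp_col[qc_pool[:n_snp]] = True
    chromosome[qc_pool[n_snp:n_snp + n_chrx]] = "chrX"

    ann = pd.DataFrame(
        {"chromosome": chromosome, "position": position, "gene": gene_col,
         "gene_region": region_col, "cgi_relation": cgi_col, "snp_flag": snp_col},
        index=pd.Index(probes, name="probe_id"),
    )

    # ---- beta means --------------------------------------------------------
    mu = np.empty((config.n_probes, n_samples))
    # null probes: one baseline per probe shared by all samples
    base_null = rng.uniform(0.05, 0.95, size=config.n_probes)
    mu[:] = base_null[:, None]

    low_base = rng.uniform(0.05, 0.15, size=ns + nsh)
    for k, p in enumerate(np.concatenate([idx_specific, idx_shared])):
        mu[p, :] = low_base[k]
    # specific markers: shifted only in target tumors
    mu[np.ix_(idx_specific, target_tumor_mask)] += config.hyper_delta
    # shared markers: shifted in every cancer type's tumors
    mu[np.ix_(idx_shared, is_tumor)] += config.hyper_delta

    # background DMCs in all cancer types
    hyper_base = rng.uniform(0.1, 0.3, size=config.n_hyper_background)
    mu[idx_hyper_bg, :] = hyper_base[:, None]
    mu[np.ix_(idx_hyper_bg, is_tumor)] += config.hyper_delta
    hypo_base = rng.uniform(0.7, 0.9, size=config.n_hypo_background)
    mu[idx_hypo_bg, :] = hypo_base[:, None]
    mu[np.ix_(idx_hypo_bg, is_tumor)] -= config.hyper_delta

    # CIMP block: normals near zero, target tumors offset by cluster
    k_clusters = config.n_cimp_clusters
    cluster_of = np.tile(np.arange(k_clusters),
                         config.n_tumors // k_clusters + 1)[: config.n_tumors]
    offsets = 0.15 + 0.30 * np.arange(k_clusters)  # separated by ~5 noise SDs
    mu[idx_cimp, :] = 0.03
    target_tumor_cols = np.flatnonzero(target_tumor_mask)
    for c in range(k_clusters):
        cols = target_tumor_cols[cluster_of == c]
        mu[np.ix_(idx_cimp, cols)] = 0.03 + offsets[c]
    mu = np.clip(mu, 0.01, 0.97)

    beta_values = _beta_noise(rng, mu, config.beta_precision)
    beta = pd.DataFrame(beta_values, index=ann.index, columns=sheet.index)

    # ---- counts ------------------------------------------------------------
    base_log_mu = rng.uniform(np.log(50.0), np.log(500.0), size=config.n_genes)
    lib_factor = rng.uniform(0.7, 1.3, size=n_samples)
    log_mu = base_log_mu[:, None] + np.log(lib_factor)[None, :]

    coupling: list[tuple[str, str, int]] = []
    marker_idx_all = np.concatenate([idx_specific, idx_shared])
    for k, p in enumerate(marker_idx_all):
        g = idx_marker_genes[k]
        b = beta_values[p, :]
        log_mu[g, :] += config.coupling_strength * (b - b.mean())
        coupling.append((probes[p], genes[g],
                         int(np.sign(config.coupling_strength))))
    for j, g in enumerate(idx_trans):
        b = beta_values[idx_specific[0], :]
        log_mu[g, :] += config.coupling_strength * (b - b.mean())
        coupling.append((probes[idx_specific[0]], genes[g],
                         int(np.sign(config.coupling_strength))))

    true_deg: dict[str, float] = {}
    signs = np.where(np.arange(config.n_direct_de) % 2 == 0, 1.0, -1.0)
    for j, g in enumerate(idx_direct_de):
        effect = signs[j] * config.direct_de_log2fc
        log_mu[g, target_tumor_mask] += effect * np.log(2.0)
        true_deg[genes[g]] = float(effect)
    # coupled genes are also DE in target tumors (through the beta shift)
    expected_coupled_lfc = config.coupling_strength * config.hyper_delta / np.log(2.0)
    for k in idx_marker_genes:
        true_deg[genes[k]] = float(expected_coupled_lfc)

    mu_counts = np.exp(log_mu)
    r = 1.0 / config.nb_dispersion
    counts_values = rng.negative_binomial(r, r / (r + mu_counts))
    counts = pd.DataFrame(counts_values.astype(np.int64),
                          index=pd.Index(genes, name="gene_id"),
                          columns=sheet.index)

    # ---- clinical covariates for target tumors (associated with clusters) --
    sheet["histology"] = pd.NA
    sheet["hpv_status"] = pd.NA
    sheet["hpv_clade"] = pd.NA
    hist_by_cluster = {0: ("adeno", "squamous"), 1: ("squamous", "adeno"),
                       2: ("squamous", "adeno")}
    for i, s in enumerate(target_tumors):
        c = int(cluster_of[i]) % 3
        major, minor = hist_by_cluster[c]
        sheet.loc[s, "histology"] = major if rng.random() < 0.85 else minor
        if c == 2:
            sheet.loc[s, "hpv_status"] = "positive" if rng.random() < 0.85 else "negative"
            sheet.loc[s, "hpv_clade"] = "A7" if rng.random() < 0.7 else "A9"
        else:
            sheet.loc[s, "hpv_status"] = "positive"
            sheet.loc[s, "hpv_clade"] = "A9" if rng.random() < 0.8 else "A7"

    truth = GroundTruth(
        specific_marker_probe_ids=[probes[p] for p in idx_specific],
        shared_marker_probe_ids=[probes[p] for p in idx_shared],
        true_deg_ids=true_deg,
        true_cluster_labels={s: int(cluster_of[i]) for i, s in enumerate(target_tumors)},
        coupling=coupling,
        hyper_background_ids=[probes[p] for p in idx_hyper_bg],
        hypo_background_ids=[probes[p] for p in idx_hypo_bg],
    )

    if config.missing_rate > 0:
        beta = inject_missing(beta, config.missing_rate,
                              seed=int(rng.integers(0, 2**31 - 1)))

    return beta, ann, counts, sheet, truth


def inject_missing(beta: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Mask a fraction *rate* of cells missing-at-random (per cell)."""
    if not 0 <= rate < 1:
        raise ValueError(f"missing rate must lie in [0, 1), got {rate}")
    out = beta.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.shape) < rate
    values = out.to_numpy(dtype=float)
    values[mask] = np.nan
    out.iloc[:, :] = values
    return out


def write_cohort(outdir, beta, ann, counts, sheet, truth) -> None:
    """Write the four pipeline inputs plus the ground-truth JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_beta_matrix(beta, outdir / "beta.tsv")
    mio.write_manifest(ann, outdir / "manifest.tsv")
    mio.write_counts(counts, outdir / "counts.tsv")
    mio.write_sample_sheet(sheet, outdir / "samples.tsv")
    truth.to_json(outdir / "truth.json")
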