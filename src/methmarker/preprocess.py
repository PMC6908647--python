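"""Probe-level QC filtering and missing-value imputation.

Filtering removes, in order of precedence, probes flagged as overlapping a
SNP, probes on chromosome X, and probes whose missing fraction exceeds the
``max_missing`` cutoff (strictly; a probe at exactly the cutoff is kept).
Each excluded probe is counted under the first matching reason so the QC
report conserves the input probe count.

Imputation replaces missing beta values by the per-probe mean.  When a sample
sheet is supplied and both conditions have at least three samples, the mean is
taken within condition, which preserves the tumor-normal group difference
used by the differential stage; otherwise the global probe mean is used.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["QCReport", "filter_probes", "impute_missing"]


@dataclass
class QCReport:
    n_input_probes: int
    n_removed_snp: int
    n_removed_chrX: int
    n_removed_missing: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = self.n_removed_snp + self.n_removed_chrX + self.n_removed_missing
        if removed + self.n_retained != self.n_input_probes:
            raise ValueError("QC report does not conserve probe count")
        if min(asdict(self).values()) < 0:
            raise ValueError("QC counts must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_probes(
    beta: pd.DataFrame,
    ann: pd.DataFrame,
    max_missing: float = 0.10,
) -> tuple[pd.DataFrame, QCReport]:
    """Drop SNP-flagged, chromosome-X and high-missingness probes."""
    unannotated = beta.index.difference(ann.index)
    if len(unannotated):
        raise KeyError(f"probe(s) missing from annotation: {list(unannotated[:5])}")

    sub = ann.loc[beta.index]
    snp = sub["snp_flag"].to_numpy(dtype=bool)
    chrx = (sub["chromosome"] == "chrX").to_numpy()
    missing_frac = beta.isna().to_numpy().mean(axis=1)
    high_missing = missing_frac > max_missing

    reason_snp = snp
    reason_chrx = chrx & ~snp
    reason_missing = high_missing & ~snp & ~chrx
    keep = ~(snp | chrx | high_missing)

    report = QCReport(
        n_input_probes=len(beta),
        n_removed_snp=int(reason_snp.sum()),
        n_removed_chrX=int(reason_chrx.sum()),
        n_removed_missing=int(reason_missing.sum()),
        n_retained=int(keep.sum()),
    )
    return beta.loc[keep], report


def impute_missing(
    beta: pd.DataFrame,
    sample_sheet: pd.DataFrame | None = None,
    min_group: int = 3,
) -> pd.DataFrame:
    """Replace missing beta values by per-probe means.

    Observed values are never touched; imputed values inherit the [0, 1]
    range from the means of observed values.
    """
    all_missing = beta.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"probe(s) with no observed values cannot be imputed: "
            f"{list(beta.index[all_missing][:5])}"
        )
    if not beta.isna().to_numpy().any():
        return beta.copy()

    out = beta.copy()
    groups: list[np.ndarray] = []
    if sample_sheet is not None:
        cond = sample_sheet.loc[out.columns, "condition"]
        masks = [(cond == c).to_numpy() for c in ("tumor", "normal")]
        if all(m.sum() >= min_group for m in masks):
            groups = masks
    if not groups:
        groups = [np.ones(out.shape[1], dtype=bool)]

    values = out.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    global_mean = np.where(observed, values, 0.0).sum(axis=1) / observed.sum(axis=1)
    for mask in groups:
        block = values[:, mask]
        obs = ~np.isnan(block)
        n_obs = obs.sum(axis=1)
        sums = np.where(obs, block, 0.0).sum(axis=1)
        # fall back to the global probe mean where a group is entirely missing
        group_mean = np.where(n_obs > 0, sums / np.maximum(n_obs, 1), global_mean)
        values[:, mask] = np.where(obs, block, group_mean[:, None])
    out.iloc[:, :] = values
    return out
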