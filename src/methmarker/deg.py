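"""TMM normalization and negative-binomial differential expression.

``tmm_factors`` implements the trimmed mean of M-values: M and A statistics
are computed on library-size-normalized counts against a reference sample
(the column whose upper quartile is closest to the mean upper quartile),
doubly trimmed (30% on M, 5% on A by default), and combined by
precision-weighted mean; factors are rescaled to geometric mean 1.

``nb_test`` fits, per gene, a negative-binomial log-linear model
``log mu = offset + b0 + b1 * group`` with offset ``log(library_size *
factor)``.  A single common dispersion is estimated by maximizing the summed
profile log-likelihood across genes (bounded scalar search on log
dispersion), and the group coefficient is tested by a likelihood-ratio
chi-square with one degree of freedom.  Fitting is Fisher scoring, vectorized
across genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .dmc import bh_adjust

__all__ = ["tmm_factors", "nb_test", "call_degs"]


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.DataFrame:
    """Trimmed-mean-of-M normalization factors, geometric mean 1.

    Returns a DataFrame indexed by sample with columns ``factor`` and
    ``library_size``.
    """
    values = counts.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = values.sum(axis=0)
    if np.any(lib == 0):
        bad = counts.columns[lib == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")

    frac = values / lib  # count fractions
    uq = np.array([np.quantile(frac[values[:, j] > 0, j], 0.75)
                   for j in range(values.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(values.shape[1])
    yr, nr = values[:, ref], lib[ref]
    for j in range(values.shape[1]):
        if j == ref:
            continue
        yj, nj = values[:, j], lib[j]
        ok = (yj > 0) & (yr > 0)
        m = np.log2((yj[ok] / nj) / (yr[ok] / nr))
        a = 0.5 * np.log2((yj[ok] / nj) * (yr[ok] / nr))
        # binomial-style asymptotic variance of M (delta method)
        v = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        v = np.maximum(v, 1e-12)  # a gene owning its whole library has v = 0
        keep = _double_trim_mask(m, a, trim_m, trim_a)
        if keep.sum() == 0:
            continue
        w = 1.0 / v[keep]
        log_factors[j] = np.sum(w * m[keep]) / np.sum(w)

    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.DataFrame({"factor": factors, "library_size": lib.astype(np.int64)},
                        index=counts.columns)


def _double_trim_mask(m: np.ndarray, a: np.ndarray,
                      trim_m: float, trim_a: float) -> np.ndarray:
    n = len(m)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    return (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)


# ---------------------------------------------------------------------------
# vectorized NB GLM, two-group design


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB log-likelihood per gene (summed over samples); alpha = dispersion."""
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-12)
    ll = (special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1.0)
          + y * np.log(mu / (mu + r)) + r * np.log(r / (mu + r)))
    return ll.sum(axis=1)


def _fit_group_model(
    y: np.ndarray, offset: np.ndarray, group: np.ndarray, alpha: float,
    with_group: bool, max_iter: int = 60, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fisher scoring for log mu = offset + b0 (+ b1*group), all genes at once.

    Returns (b0, b1, loglik per gene).
    """
    g1 = group.astype(bool)
    eo = np.exp(offset)
    # moment-style init from group mean ratios
    mean0 = (y[:, ~g1].sum(axis=1) + 0.5) / eo[~g1].sum()
    b0 = np.log(mean0)
    if with_group:
        mean1 = (y[:, g1].sum(axis=1) + 0.5) / eo[g1].sum()
        b1 = np.log(mean1) - b0
    else:
        b1 = np.zeros_like(b0)

    for _ in range(max_iter):
        eta = offset[None, :] + b0[:, None] + b1[:, None] * group[None, :]
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha * mu)          # Fisher weight wrt eta
        r = (y - mu) / (1.0 + alpha * mu)    # score contribution wrt eta
        if with_group:
            s0 = r.sum(axis=1)
            s1 = r[:, g1].sum(axis=1)
            h00 = w.sum(axis=1)
            h01 = w[:, g1].sum(axis=1)
            h11 = h01
            det = h00 * h11 - h01 * h01
            det = np.where(np.abs(det) < 1e-12, 1e-12, det)
            d0 = (h11 * s0 - h01 * s1) / det
            d1 = (h00 * s1 - h01 * s0) / det
        else:
            h00 = np.maximum(w.sum(axis=1), 1e-12)
            d0 = r.sum(axis=1) / h00
            d1 = np.zeros_like(d0)
        d0 = np.clip(d0, -5, 5)
        d1 = np.clip(d1, -5, 5)
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(initial=0.0), np.abs(d1).max(initial=0.0)) < tol:
            break
    eta = offset[None, :] + b0[:, None] + b1[:, None] * group[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    return b0, b1, _nb_loglik(y, mu, alpha)


def estimate_common_dispersion(
    y: np.ndarray, offset: np.ndarray, group: np.ndarray,
    bounds: tuple[float, float] = (1e-6, 10.0), xtol: float = 1e-6,
) -> float:
    """Common NB dispersion maximizing the summed profile log-likelihood."""

    def neg_profile(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        _, _, ll = _fit_group_model(y, offset, group, alpha, with_group=True)
        return -float(ll.sum())

    res = optimize.minimize_scalar(
        neg_profile, bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded", options={"xatol": xtol},
    )
    return float(np.exp(res.x))


def nb_test(
    counts: pd.DataFrame,
    factors: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-gene NB GLM likelihood-ratio test of the tumor-vs-normal coefficient.

    Returns a DataFrame indexed by gene with columns ``log2_fc``, ``p_value``,
    ``fdr``, ``all_zero`` and attrs ``dispersion``.
    """
    if isinstance(groups, pd.Series):
        groups = groups.loc[counts.columns]
    g = np.asarray(groups)
    tumor = g if g.dtype == bool else (g == "tumor")
    if tumor.sum() < 2 or (~tumor).sum() < 2:
        raise ValueError("both groups need at least 2 samples")

    y = counts.to_numpy(dtype=float)
    f = factors.loc[counts.columns, "factor"].to_numpy(dtype=float)
    lib = factors.loc[counts.columns, "library_size"].to_numpy(dtype=float)
    offset = np.log(lib * f)
    group = tumor.astype(float)

    nonzero = y.sum(axis=1) > 0
    yz = y[nonzero]
    if dispersion is None:
        dispersion = estimate_common_dispersion(yz, offset, group)

    b0, b1, ll_full = _fit_group_model(yz, offset, group, dispersion, with_group=True)
    _, _, ll_null = _fit_group_model(yz, offset, group, dispersion, with_group=False)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)

    log2_fc = np.zeros(len(counts))
    p_all = np.ones(len(counts))
    log2_fc[nonzero] = b1 / np.log(2.0)
    p_all[nonzero] = p
    out = pd.DataFrame(
        {"log2_fc": log2_fc, "p_value": p_all, "fdr": bh_adjust(p_all),
         "all_zero": ~nonzero},
        index=counts.index,
    )
    out.attrs["dispersion"] = float(dispersion)
    return out


def call_degs(
    stats_table: pd.DataFrame,
    lfc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Up/down DEG sets: |log2 FC| strictly > threshold and FDR < threshold."""
    keep = (stats_table["log2_fc"].abs() > lfc_threshold) & (
        stats_table["fdr"] < fdr_threshold
    )
    sub = stats_table.loc[keep]
    up = set(sub.index[sub["log2_fc"] > 0])
    down = set(sub.index[sub["log2_fc"] < 0])
    return up, down
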