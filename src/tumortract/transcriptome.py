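"""Tract-associated biopsy expression analysis.

The stage starts from a gene-by-sample counts matrix (alignment and gene
summarization are upstream expectations: reads mapped with quality >= 20,
summarized per gene).  It applies:

1. CPM filtering — retain genes with at least ``min_cpm`` counts-per-million
   in at least ``min_samples`` samples (default 5 CPM in 2 samples);
2. hierarchical clustering of samples on Euclidean distance of log2-CPM
   profiles with average linkage;
3. voom-style differential expression — log2-CPM with a 0.5-count offset, a
   lowess trend of sqrt residual standard deviation against mean log-count,
   per-observation precision weights trend(fitted)^-4, weighted least
   squares per gene, and moderated t-statistics via empirical-Bayes variance
   shrinkage (method-of-moments fit of a scaled inverse-chi-square prior);
4. Benjamini-Hochberg FDR adjustment and a combined |fold change| >= 2,
   q < 0.05 differential-expression call;
5. exact hypergeometric over-representation of a user-supplied gene set
   (e.g. cell-motility genes) in the DE set.

The default contrast is "tract versus rest": tract-associated samples
against the pooled tumor-bulk and normal samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .phantom import CountsMatrix

__all__ = [
    "cpm_filter",
    "hier_cluster",
    "voom_de",
    "bh_adjust",
    "de_call",
    "ora_fisher",
    "log2_cpm",
]


def _library_sizes(counts: pd.DataFrame) -> np.ndarray:
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    return lib


def cpm_filter(
    cm: CountsMatrix,
    min_cpm: float = 5.0,
    min_samples: int = 2,
    literal: bool = False,
) -> CountsMatrix:
    """Filter genes by counts-per-million.

    Default rule (the standard reading): retain genes with CPM >= ``min_cpm``
    in at least ``min_samples`` samples.  ``literal=True`` applies the
    alternative literal reading — discard genes whose CPM falls below
    ``min_cpm`` in at least ``min_samples`` samples.  All samples are kept.
    """
    counts = cm.counts
    lib = _library_sizes(counts)
    cpm = counts.to_numpy(dtype=float) * 1e6 / lib[None, :]
    if literal:
        keep = (cpm < min_cpm).sum(axis=1) < min_samples
    else:
        keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            f"no gene passes CPM >= {min_cpm} in >= {min_samples} samples; "
            "check library sizes and thresholds"
        )
    truth = cm.true_fold_change
    return CountsMatrix(
        counts=counts.loc[keep],
        sample_groups=cm.sample_groups,
        true_fold_change=truth.loc[keep] if truth is not None else None,
    )


def log2_cpm(counts: pd.DataFrame, lib: np.ndarray | None = None) -> pd.DataFrame:
    """log2 counts-per-million with the voom 0.5-count / +1-library offset."""
    if lib is None:
        lib = _library_sizes(counts)
    vals = np.log2((counts.to_numpy(dtype=float) + 0.5) / (lib[None, :] + 1.0) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def hier_cluster(logcpm: pd.DataFrame, k: int | None = None) -> dict:
    """Average-linkage hierarchical clustering of samples.

    Distances are Euclidean between per-sample log2-CPM profiles.  Returns
    the scipy linkage matrix and, when ``k`` is given, flat labels (ties in
    merge heights are broken deterministically by scipy's ordering, which
    follows sample index).
    """
    if logcpm.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    profiles = logcpm.to_numpy(dtype=float).T  # samples x genes
    Z = hierarchy.linkage(profiles, method="average", metric="euclidean")
    out = {"linkage": Z, "samples": list(logcpm.columns)}
    if k is not None:
        out["labels"] = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of gene variances toward a common prior.

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the observed
    residual variances by matching the mean and variance of log(s^2)
    (method of moments on the log-F distribution), then returns the
    posterior variances (d0*s0^2 + df*s^2) / (d0 + df) together with
    (d0, s0^2).  d0 = inf collapses every variance to s0^2.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s20 = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
        post = (d0 * s20 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s20 = np.exp(emean)
        post = np.full_like(s2, s20)
    return post, d0, s20


def voom_de(
    cm: CountsMatrix,
    contrast: str = "tract",
    lib: np.ndarray | None = None,
    lowess_frac: float = 0.5,
) -> pd.DataFrame:
    """Precision-weighted differential expression of ``contrast`` vs rest.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (contrast
    group minus the rest), ``t`` (moderated), ``p`` (two-sided), ``q``
    (Benjamini-Hochberg), and ``ave_logcpm``.

    ``lib`` overrides the library sizes (by default the column sums of the
    supplied — typically already filtered — matrix; pass raw column sums to
    normalize by pre-filter totals).
    """
    counts = cm.counts
    groups = cm.sample_groups
    is_c = (groups == contrast).to_numpy()
    if is_c.sum() < 2 or (~is_c).sum() < 2:
        raise ValueError("each side of the contrast needs >= 2 samples")
    n_genes, n_samples = counts.shape
    if lib is None:
        lib = _library_sizes(counts)
    lib = np.asarray(lib, dtype=float)

    y = log2_cpm(counts, lib).to_numpy()                 # (G, S)
    X = np.column_stack([np.ones(n_samples), is_c.astype(float)])
    df_resid = n_samples - 2

    # initial OLS per gene (shared design -> one pinv)
    pinv = np.linalg.pinv(X)                             # (2, S)
    beta = y @ pinv.T                                    # (G, 2)
    fitted = beta @ X.T                                  # (G, S)
    resid = y - fitted
    s2 = (resid ** 2).sum(axis=1) / df_resid

    # mean-variance trend: sqrt(sd) versus average log2 count
    log2_lib = np.log2(lib + 1.0).mean()
    sx = y.mean(axis=1) + log2_lib - np.log2(1e6)        # mean log2 count
    sy = np.sqrt(np.sqrt(s2))
    lo = sm.nonparametric.lowess(sy, sx, frac=lowess_frac, return_sorted=True)
    lx, ly = lo[:, 0], np.maximum(lo[:, 1], 1e-6)

    # per-observation weights from fitted log-counts
    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    trend = np.interp(fitted_logcount, lx, ly)
    w = trend ** -4.0                                    # (G, S)

    # weighted least squares per gene (2x2 normal equations, vectorized)
    x1 = X[:, 1]
    sw = w.sum(axis=1)
    swx = w @ x1
    swx2 = w @ (x1 ** 2)
    swy = (w * y).sum(axis=1)
    swxy = (w * y * x1[None, :]).sum(axis=1)
    det = sw * swx2 - swx ** 2
    b0 = (swx2 * swy - swx * swxy) / det
    b1 = (sw * swxy - swx * swy) / det
    fitted_w = b0[:, None] + b1[:, None] * x1[None, :]
    rss = (w * (y - fitted_w) ** 2).sum(axis=1)
    s2_w = rss / df_resid
    # unscaled stdev of the contrast coefficient: sqrt([ (X'WX)^-1 ]_11)
    se_unscaled = np.sqrt(sw / det)

    s2_post, d0, _ = _squeeze_var(s2_w, df_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = b1 / (se_unscaled * np.sqrt(s2_post))
    df_total = df_resid + (0.0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": b1,
            "t": tstat,
            "p": pvals,
            "q": bh_adjust(pvals),
            "ave_logcpm": y.mean(axis=1),
        },
        index=counts.index,
    )
    return table


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def de_call(
    table: pd.DataFrame,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differentially expressed genes at |fold change| >= ``fc_threshold``
    and q < ``q_threshold``; the returned frame records the direction."""
    sel = (np.abs(table["log2fc"]) >= np.log2(fc_threshold)) & (
        table["q"] < q_threshold
    )
    out = table.loc[sel].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def ora_fisher(de_set, annotation_set, universe) -> dict:
    """One-sided exact over-representation test of ``annotation_set`` in
    ``de_set`` within ``universe`` (hypergeometric tail for overlap >=
    observed) plus the sample odds ratio of the 2x2 table."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    de = set(de_set) & universe
    ann = set(annotation_set) & universe
    if set(de_set) - universe or set(annotation_set) - universe:
        raise ValueError("de_set and annotation_set must be subsets of universe")
    m = len(universe)
    n_de = len(de)
    n_ann = len(ann)
    overlap = len(de & ann)
    p = float(stats.hypergeom.sf(overlap - 1, m, n_ann, n_de))
    a = overlap
    b = n_de - overlap
    c = n_ann - overlap
    d = m - n_de - n_ann + overlap
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return {
        "overlap": overlap,
        "set_size": n_ann,
        "universe_size": m,
        "de_count": n_de,
        "odds_ratio": float(odds),
        "p": min(p, 1.0) if p > 0 else np.nextafter(0, 1),
    }
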