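"""Gene-expression variability: CV2 against mean, loess residuals, and tests.

Variability is quantified per population as the residual of log CV2
(CV2 = sigma^2 / mu^2 of normalized counts across samples) from a local
quadratic (tricube-weighted) regression on log mean expression — genes
above the trend are more variable than expected for their expression
level.  Counts are normalized by median-of-ratios size factors.  A
minimal negative-binomial Wald differential-expression stage is included
as plumbing so overlap statistics with methylation calls can be computed.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .differential_methylation import bh_adjust

log = logging.getLogger("methylvar")


def filter_low_expression(counts: pd.DataFrame, min_count: int = 15,
                          max_frac_below: float = 0.90) -> pd.DataFrame:
    """Drop genes with < min_count reads in more than max_frac_below of samples."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    n = counts.shape[1]
    n_below = (counts < min_count).sum(axis=1)
    keep = n_below <= max_frac_below * n
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_s = median over genes (nonzero in all samples) of
    count_gs / geometric-mean_g(count).
    """
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene expressed in all samples")
    logx = np.log(x[allpos])
    log_gm = logx.mean(axis=1, keepdims=True)
    log_f = np.median(logx - log_gm, axis=0)
    log_f -= log_f.mean()      # rescale to geometric mean 1
    return pd.Series(np.exp(log_f), index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame,
                     factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def cv2_per_gene(normalized: pd.DataFrame,
                 sample_subset=None) -> pd.DataFrame:
    """Per-gene mean and squared coefficient of variation CV2 = s^2 / mu^2.

    Uses the unbiased sample variance; genes with mu <= 0 are skipped.
    Requires at least 3 samples in the subset.
    """
    sub = normalized if sample_subset is None else normalized[list(sample_subset)]
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples for CV2")
    mu = sub.mean(axis=1)
    var = sub.var(axis=1, ddof=1)
    keep = mu > 0
    if (~keep).any():
        log.warning("skipping %d genes with zero mean expression", int((~keep).sum()))
    out = pd.DataFrame({"mu": mu[keep], "cv2": (var / mu**2)[keep]})
    out.index.name = "gene_id"
    return out


def loess_smooth(x, y, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Local polynomial regression (tricube weights) evaluated at x.

    Classic loess: for each point, fit a weighted degree-``degree``
    polynomial on the span*n nearest neighbours.  No robustness
    iterations (the CV2-trend fit does not need them).
    """
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    # k nearest neighbours of a sorted point form a contiguous window
    starts = np.empty(n, dtype=int)
    l = 0
    for i in range(n):
        while l + k < n and xs[l + k] - xs[i] < xs[i] - xs[l]:
            l += 1
        starts[i] = l
    idx = starts[:, None] + np.arange(k)[None, :]
    xl = xs[idx] - xs[:, None]
    d = np.abs(xl)
    dmax = d.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(dmax > 0, d / dmax, 0.0)
    w = (1 - u**3) ** 3
    A = np.stack([xl**j for j in range(degree + 1)], axis=2)  # (n, k, d+1)
    Aw = A * w[:, :, None]
    G = np.einsum("nkp,nkq->npq", Aw, A)
    b = np.einsum("nkp,nk->np", Aw, ys[idx])
    G += 1e-12 * np.eye(degree + 1)[None]
    beta = np.linalg.solve(G, b[..., None])[..., 0]
    fitted_sorted = beta[:, 0]
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


def loess_residual_variability(cv2_table: pd.DataFrame, span: float = 0.75,
                               population: str = "pooled",
                               log_scale: bool = True) -> pd.DataFrame:
    """Fit the CV2 ~ mean trend and extract per-gene residual variability.

    Default fits log(CV2) on log(mu); residuals are on the log scale, so a
    gene with twice the trend CV2 sits ~log(2) above zero.  Raw-scale mode
    fits CV2 on mu directly.  Requires >= 50 genes.
    """
    if len(cv2_table) < 50:
        raise ValueError("need >= 50 genes to fit the variability trend")
    tab = cv2_table.copy()
    if log_scale:
        ok = tab["cv2"] > 0
        if (~ok).any():
            log.warning("dropping %d genes with CV2 = 0 from the log-scale fit",
                        int((~ok).sum()))
            tab = tab[ok]
        fit = loess_smooth(np.log(tab["mu"]), np.log(tab["cv2"]), span=span)
        tab["predicted_cv2"] = np.exp(fit)
        tab["residual"] = np.log(tab["cv2"].to_numpy()) - fit
    else:
        fit = loess_smooth(tab["mu"], tab["cv2"], span=span)
        tab["predicted_cv2"] = fit
        tab["residual"] = tab["cv2"].to_numpy() - fit
    tab["population"] = population
    return tab


def variability_by_population(counts: pd.DataFrame, design: pd.DataFrame,
                              span: float = 0.75,
                              log_scale: bool = True) -> pd.DataFrame:
    """Per-population variability tables (long format), pooled environments."""
    factors = size_factors(counts)
    norm = normalize_counts(counts, factors)
    rna = design[design["assay"] == "RNA"]
    pieces = []
    for pop, sub in rna.groupby("population"):
        tab = cv2_per_gene(norm, sub["sample_id"].tolist())
        pieces.append(loess_residual_variability(tab, span=span,
                                                 population=pop,
                                                 log_scale=log_scale))
    return pd.concat(pieces)


def compare_sets_variability(table: pd.DataFrame, set_a, set_b=None,
                             paired: bool = False) -> dict:
    """Compare residual variability between gene sets.

    Unpaired: two-sided rank-sum of residuals of set A vs set B within one
    population's table.  Paired: per-gene difference of residuals
    (FC - NC) computed from a two-population table; set A's differences
    are tested by two-sided signed-rank (against set B's differences by
    rank-sum when B is given).
    """
    set_a = set(set_a)
    if not paired:
        set_b = set(set_b)
        if set_a & set_b:
            raise ValueError("sets must be disjoint for the unpaired test")
        a = table.loc[table.index.isin(set_a), "residual"].to_numpy()
        b = table.loc[table.index.isin(set_b), "residual"].to_numpy()
        if len(a) < 3 or len(b) < 3:
            raise ValueError("need >= 3 genes per set")
        stat, p = stats.ranksums(a, b)
        direction = "A lower" if np.median(a) < np.median(b) else "A higher"
        return {"p": float(p), "stat": float(stat), "direction": direction,
                "n_a": len(a), "n_b": len(b),
                "median_diff": float(np.median(a) - np.median(b))}

    pops = table["population"].unique()
    if len(pops) != 2:
        raise ValueError("paired comparison needs a two-population table")
    wide = table.pivot_table(index=table.index, columns="population",
                             values="residual")
    wide = wide.dropna()
    diffs = wide["FC"] - wide["NC"]
    d_a = diffs[diffs.index.isin(set_a)].to_numpy()
    if len(d_a) < 3:
        raise ValueError("need >= 3 genes per set")
    if set_b is not None:
        d_b = diffs[diffs.index.isin(set(set_b))].to_numpy()
        if len(d_b) < 3:
            raise ValueError("need >= 3 genes per set")
        stat, p = stats.ranksums(d_a, d_b)
        direction = ("A lower" if np.median(d_a) < np.median(d_b)
                     else "A higher")
        return {"p": float(p), "stat": float(stat), "direction": direction,
                "n_a": len(d_a), "n_b": len(d_b),
                "median_diff": float(np.median(d_a) - np.median(d_b))}
    if np.allclose(d_a, 0):
        log.warning("all paired differences are zero; signed-rank degenerate")
        return {"p": 1.0, "stat": 0.0, "direction": "none", "n_a": len(d_a),
                "n_b": 0, "median_diff": 0.0}
    stat, p = stats.wilcoxon(d_a)
    direction = "FC lower" if np.median(d_a) < 0 else "FC higher"
    return {"p": float(p), "stat": float(stat), "direction": direction,
            "n_a": len(d_a), "n_b": 0, "median_diff": float(np.median(d_a))}


def simple_de(counts: pd.DataFrame, condition, lfc_threshold: float = 1.0,
              alpha: float = 0.05) -> pd.DataFrame:
    """Minimal two-group differential expression on normalized counts.

    log2 fold change of group means (0.5 pseudocount), negative-binomial
    Wald test with a method-of-moments gene-wise dispersion, BH-adjusted;
    a gene is a DEG iff q < alpha AND |log2FC| >= lfc_threshold.  This is
    declared plumbing: a deliberately simple stage whose output feeds
    overlap statistics only.
    """
    condition = np.asarray(condition)
    levels = np.unique(condition)
    if len(levels) != 2:
        raise ValueError("expected exactly 2 condition levels")
    g1 = condition == levels[0]
    g2 = condition == levels[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("need >= 2 samples per condition")
    norm = normalize_counts(counts).to_numpy(dtype=float)
    x1, x2 = norm[:, g1], norm[:, g2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log2fc = np.log2((m2 + 0.5) / (m1 + 0.5))
    # pooled method-of-moments NB dispersion: var = mu + alpha mu^2
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        a1 = (v1 - m1) / m1**2
        a2 = (v2 - m2) / m2**2
    disp = np.nanmean(np.column_stack([a1, a2]), axis=1)
    disp = np.clip(np.nan_to_num(disp, nan=0.0), 0.0, None)
    var_log1 = (m1 + disp * m1**2) / np.clip(g1.sum() * m1**2, 1e-12, None)
    var_log2 = (m2 + disp * m2**2) / np.clip(g2.sum() * m2**2, 1e-12, None)
    se = np.sqrt(var_log1 + var_log2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.log((m2 + 0.5) / (m1 + 0.5)) / se
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_adjust(p)
    out = pd.DataFrame({"mean_1": m1, "mean_2": m2, "log2fc": log2fc,
                        "p": p, "q": q},
                       index=counts.index)
    out["is_deg"] = (out["q"] < alpha) & (np.abs(out["log2fc"]) >= lfc_threshold)
    return out
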