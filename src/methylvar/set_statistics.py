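"""Shared inferential utilities: overlaps, slope-vs-1, SNP divergence, chi-square."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class OverlapResult:
    """2x2 membership table of two gene sets over a shared universe.

    a = both, b = A only, c = B only, d = neither.  The odds ratio is the
    sample (unconditional) OR; a Haldane-Anscombe 0.5 correction is applied
    iff any cell is zero (flagged).  p is the two-sided exact conditional
    (hypergeometric) p-value.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    log2_odds_ratio: float
    p: float
    continuity_corrected: bool

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("a", "b", "c", "d", "odds_ratio", "log2_odds_ratio", "p",
                 "continuity_corrected")}


def fisher_overlap(set_a, set_b, universe) -> OverlapResult:
    """Fisher's exact test of overlap between two gene sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = ((x + 0.5 for x in (a, b, c, d)) if corrected
                      else (a, b, c, d))
    odds = (aa * dd) / (bb * cc)
    return OverlapResult(a, b, c, d, float(odds), float(np.log2(odds)),
                         float(p), corrected)


@dataclass
class SlopeResult:
    slope: float
    intercept: float
    t_slope: float
    p_slope_ne_0: float
    t_slope_ne_1: float
    p_slope_ne_1: float
    n: int


def slope_vs_one(x, y) -> SlopeResult:
    """OLS slope of y on x with tests against 0 and against 1.

    The slope-vs-1 test refits (y - x) ~ x, whose slope is slope - 1; a
    perfect y = x gives test statistic 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 pairs")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    X = sm.add_constant(x)
    fit0 = sm.OLS(y, X).fit()
    fit1 = sm.OLS(y - x, X).fit()

    def _tp(fit):
        coef, se = fit.params[1], fit.bse[1]
        if se == 0 or not np.isfinite(se):
            t = 0.0 if abs(coef) < 1e-12 else np.inf * np.sign(coef)
        else:
            t = coef / se
        p = (1.0 if t == 0 else
             float(2 * stats.t.sf(abs(t), len(x) - 2)))
        return float(t), p

    t0, p0 = _tp(fit0)
    t1, p1 = _tp(fit1)
    return SlopeResult(float(fit0.params[1]), float(fit0.params[0]),
                       t0, p0, t1, p1, len(x))


def snp_divergence(freqs: pd.DataFrame, hi: float = 0.8,
                   lo: float = 0.2) -> pd.DataFrame:
    """Flag genes with a SNP fixed apart between populations.

    ``freqs`` needs columns gene_id, freq_pop1, freq_pop2 (one row per
    SNP).  A gene is divergent iff some SNP has frequency > hi in one
    population and < lo in the other (strict, symmetric in populations).
    """
    f1 = freqs["freq_pop1"].to_numpy(dtype=float)
    f2 = freqs["freq_pop2"].to_numpy(dtype=float)
    if ((f1 < 0) | (f1 > 1) | (f2 < 0) | (f2 > 1)).any():
        raise ValueError("allele frequencies must be in [0, 1]")
    snp_div = ((f1 > hi) & (f2 < lo)) | ((f2 > hi) & (f1 < lo))
    out = (pd.DataFrame({"gene_id": freqs["gene_id"], "snp_divergent": snp_div})
           .groupby("gene_id")["snp_divergent"].any()
           .rename("is_divergent").reset_index())
    return out


def divergent_gene_set(freqs: pd.DataFrame, hi: float = 0.8,
                       lo: float = 0.2) -> set:
    calls = snp_divergence(freqs, hi, lo)
    return set(calls.loc[calls["is_divergent"], "gene_id"])


def chisq_counts(table) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table; (statistic, df, p)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D")
    expected = (table.sum(axis=1, keepdims=True)
                * table.sum(axis=0, keepdims=True) / table.sum())
    if (expected <= 0).any():
        raise ValueError("zero expected count")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)
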