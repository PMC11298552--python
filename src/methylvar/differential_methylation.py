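"""Gene-level differential methylation with an empirical permutation FDR.

Each gene's aggregated methylated/total read counts are modelled with a
weighted binomial GLM (logistic link, prior weights = total reads); the
condition coefficient is tested by Wald test, Benjamini-Hochberg corrected,
and genes with adjusted p below the threshold (default 0.01) are called
differentially methylated.  The overall false-discovery behaviour is then
assessed empirically by shuffling sample labels between conditions and
re-running the identical pipeline at every shuffle.

The GLM is an IRLS fit vectorized across genes (all genes share the design
matrix), which is what makes 1000-shuffle permutation runs cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("methylvar")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    NaN entries are passed through and excluded from the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    obs = ~np.isnan(p)
    pv = p[obs]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if pv.size:
        out[obs] = multipletests(pv, method="fdr_bh")[1]
    return out


def _design_matrix(condition, block=None):
    condition = np.asarray(condition)
    levels = np.unique(condition)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 condition levels, got {levels}")
    cond01 = (condition == levels[1]).astype(float)
    cols = [np.ones(len(condition)), cond01]
    if block is not None:
        block = np.asarray(block)
        for b in np.unique(block)[1:]:
            cols.append((block == b).astype(float))
    X = np.column_stack(cols)
    return X, levels


def weighted_binomial_glm(M, T, condition, block=None, quasi: bool = False,
                          max_iter: int = 60, tol: float = 1e-10) -> pd.DataFrame:
    """Weighted binomial GLM of methylation proportion on condition, per gene.

    M, T: gene x sample frames (or arrays) of methylated / total read
    counts.  The coefficient is the log-odds difference, second condition
    level (sorted order) minus the first; p is a Wald p-value.  Genes where
    a condition has all-0% or all-100% methylation (complete separation)
    get a 0.5-read continuity correction and are flagged.  ``quasi``
    switches to a quasi-binomial scale estimate with t-based p-values.
    """
    genes = M.index if isinstance(M, pd.DataFrame) else pd.RangeIndex(len(M))
    M = np.asarray(M, dtype=float)
    T = np.asarray(T, dtype=float)
    X, levels = _design_matrix(condition, block)
    n_g, n_s = M.shape
    p_dim = X.shape[1]
    cond01 = X[:, 1].astype(bool)

    covered = T > 0
    valid = ((covered & ~cond01[None, :]).sum(axis=1) >= 2) \
        & ((covered & cond01[None, :]).sum(axis=1) >= 2)

    # complete-separation guard: a condition entirely at 0% or 100%
    def _all_extreme(side):
        cols = covered & side[None, :]
        m_in = np.where(cols, M, np.nan)
        t_in = np.where(cols, T, np.nan)
        with np.errstate(invalid="ignore"):
            all0 = np.nanmax(m_in, axis=1) == 0
            all1 = np.nanmax(t_in - m_in, axis=1) == 0
        return all0 | all1

    separated = valid & (_all_extreme(~cond01) | _all_extreme(cond01))
    Mw = M.copy()
    Tw = T.copy()
    corr = separated[:, None] & covered
    Mw[corr] += 0.5
    Tw[corr] += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(Tw > 0, Mw / Tw, 0.0)

    beta = np.zeros((n_g, p_dim))
    active = valid.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        eta = np.clip(beta @ X.T, -30, 30)
        mu = special.expit(eta)
        w = Tw * mu * (1 - mu)
        w[~covered] = 0.0
        z = eta + (y - mu) / np.clip(mu * (1 - mu), 1e-12, None)
        XtWX = np.einsum("sp,gs,sq->gpq", X, w, X)
        XtWz = np.einsum("sp,gs,gs->gp", X, w, z)
        XtWX += 1e-10 * np.eye(p_dim)[None, :, :]
        new = np.linalg.solve(XtWX[active], XtWz[active][..., None])[..., 0]
        delta = np.max(np.abs(new - beta[active]), axis=1)
        beta[active] = new
        still = np.zeros(n_g, dtype=bool)
        still[np.flatnonzero(active)[delta >= tol]] = True
        active = still

    eta = np.clip(beta @ X.T, -30, 30)
    mu = special.expit(eta)
    w = Tw * mu * (1 - mu)
    w[~covered] = 0.0
    XtWX = np.einsum("sp,gs,sq->gpq", X, w, X) + 1e-10 * np.eye(p_dim)[None]
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(cov[:, 1, 1], 0.0))

    coef = beta[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        zstat = coef / se
    if quasi:
        resid2 = Tw * (y - mu) ** 2 / np.clip(mu * (1 - mu), 1e-12, None)
        resid2[~covered] = 0.0
        df = covered.sum(axis=1) - p_dim
        disp = np.where(df > 0, resid2.sum(axis=1) / np.maximum(df, 1), 1.0)
        disp = np.maximum(disp, 1.0e-8)
        zstat = zstat / np.sqrt(disp)
        pval = 2 * stats.t.sf(np.abs(zstat), np.maximum(df, 1))
    else:
        pval = 2 * stats.norm.sf(np.abs(zstat))

    coef = np.where(valid, coef, np.nan)
    pval = np.where(valid, pval, np.nan)
    se = np.where(valid, se, np.nan)
    return pd.DataFrame({"coef": coef, "se": se, "p": pval,
                         "separation": separated},
                        index=pd.Index(genes, name="gene_id"))


def call_dmgs(results: pd.DataFrame, alpha: float = 0.01) -> set:
    """Genes with BH-adjusted p strictly below alpha."""
    if "q" not in results.columns:
        raise ValueError("results must carry a q column (run dmg_test)")
    return set(results.index[results["q"] < alpha])


def dmg_test(M, T, condition, block=None, alpha: float = 0.01,
             quasi: bool = False) -> pd.DataFrame:
    """GLM + BH + threshold in one step; returns the DMG result table."""
    res = weighted_binomial_glm(M, T, condition, block=block, quasi=quasi)
    res["q"] = bh_adjust(res["p"])
    res["is_dmg"] = res["q"] < alpha
    return res


@dataclass
class EmpiricalFDRResult:
    """Observed DMG count against a shuffled-label null distribution."""

    observed_dmg_count: int
    null_counts: np.ndarray
    p_empirical: float
    p_empirical_add_one: float
    n_shuffles: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "observed_dmg_count": int(self.observed_dmg_count),
            "null_counts": [int(c) for c in self.null_counts],
            "p_empirical": self.p_empirical,
            "p_empirical_add_one": self.p_empirical_add_one,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
        }


def empirical_fdr(M, T, condition, block=None, n_shuffles: int = 1000,
                  seed: int | None = None, alpha: float = 0.01,
                  quasi: bool = False) -> EmpiricalFDRResult:
    """Shuffle sample labels between conditions and re-run the DMG pipeline.

    Shuffles are uniform over label assignments with the observed group
    sizes (a shuffle may coincide with the observed labelling).  The
    plug-in estimator #{null >= observed}/n_shuffles can be exactly 0; the
    add-one estimator is reported alongside.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    condition = np.asarray(condition)
    rng = np.random.default_rng(seed)
    observed = len(call_dmgs(dmg_test(M, T, condition, block=block,
                                      alpha=alpha, quasi=quasi), alpha))
    null_counts = np.empty(n_shuffles, dtype=int)
    for i in range(n_shuffles):
        perm = rng.permutation(len(condition))
        res = dmg_test(M, T, condition[perm], block=block, alpha=alpha,
                       quasi=quasi)
        null_counts[i] = len(call_dmgs(res, alpha))
    p_emp = float(np.mean(null_counts >= observed))
    p_add1 = float((np.sum(null_counts >= observed) + 1) / (n_shuffles + 1))
    return EmpiricalFDRResult(observed, null_counts, p_emp, p_add1,
                              n_shuffles, seed)
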