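"""Within-gene CpG co-methylation versus a between-gene shuffle null.

Coordinated methylation change shows up as correlated methylation profiles
of CpGs within the same gene across samples.  The statistic: draw 100
genes at random from a gene set, enumerate all unordered CpG pairs within
each gene, compute pairwise Pearson correlations of methylation fractions
across samples, and record the per-repeat mean; repeat 100 times.  The
null does the same after uniformly shuffling the CpG -> gene assignment
within the drawn set, so pairs straddle genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CpGMatrix

log = logging.getLogger("methylvar")


@dataclass
class CorrelationSummary:
    mode: str                       # within_gene | between_gene_null
    gene_set_label: str
    per_repeat_mean: np.ndarray     # NaN for repeats with no eligible pairs
    pooled: np.ndarray              # all pair correlations, all repeats
    n_genes_per_repeat: int
    n_repeats: int
    seed: int | None
    samples: list[str] = field(default_factory=list)

    @property
    def pooled_mean(self) -> float:
        return float(np.mean(self.pooled)) if len(self.pooled) else np.nan


def pairwise_correlations(frac: np.ndarray,
                          min_samples: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson correlations between rows of ``frac``.

    NaN cells are treated as missing; pairs with fewer than ``min_samples``
    joint observations, or with a constant profile on the joint support,
    are NaN.  Returns (r, n_joint), both (c, c).
    """
    V = np.isfinite(frac).astype(float)
    X = np.where(np.isfinite(frac), frac, 0.0)
    X2 = X * X
    n = V @ V.T
    Sx = X @ V.T          # sum of x over joint support, for each (i, j)
    Sy = Sx.T
    Sxx = X2 @ V.T
    Syy = Sxx.T
    Sxy = X @ X.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * Sxy - Sx * Sy
        varx = n * Sxx - Sx**2
        vary = n * Syy - Sy**2
        r = cov / np.sqrt(varx * vary)
    bad = (n < min_samples) | (varx <= 0) | (vary <= 0)
    r = np.where(bad, np.nan, r)
    return r, n


def _gene_cpg_rows(mapping: pd.DataFrame, gene_set) -> dict:
    sub = mapping[mapping["gene_id"].isin(set(gene_set))]
    groups = {g: idx.to_numpy()
              for g, idx in sub.groupby("gene_id")["site_idx"]}
    return {g: rows for g, rows in groups.items() if len(rows) >= 2}


def within_gene_pair_correlations(matrix: CpGMatrix, mapping: pd.DataFrame,
                                  gene_set, n_genes: int = 100,
                                  n_repeats: int = 100, min_samples: int = 4,
                                  seed: int | None = None,
                                  gene_set_label: str = "") -> CorrelationSummary:
    """Mean within-gene CpG pair correlation over random gene subsamples."""
    groups = _gene_cpg_rows(mapping, gene_set)
    eligible = sorted(groups)
    if n_genes > len(eligible):
        raise ValueError(
            f"n_genes={n_genes} exceeds {len(eligible)} eligible genes "
            "(>= 2 assigned CpGs)")
    frac = matrix.fractions()
    iu_cache: dict[str, np.ndarray] = {}
    for g in eligible:
        r, _ = pairwise_correlations(frac[groups[g]], min_samples)
        iu_cache[g] = r[np.triu_indices(len(groups[g]), k=1)]
    rng = np.random.default_rng(seed)
    per_repeat = np.full(n_repeats, np.nan)
    pooled = []
    for rep in range(n_repeats):
        chosen = rng.choice(eligible, size=n_genes, replace=False)
        vals = np.concatenate([iu_cache[g] for g in chosen])
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            log.warning("repeat %d: no eligible CpG pairs", rep)
            continue
        per_repeat[rep] = vals.mean()
        pooled.append(vals)
    return CorrelationSummary(
        mode="within_gene", gene_set_label=gene_set_label,
        per_repeat_mean=per_repeat,
        pooled=np.concatenate(pooled) if pooled else np.array([]),
        n_genes_per_repeat=n_genes, n_repeats=n_repeats, seed=seed,
        samples=list(matrix.samples))


def between_gene_null(matrix: CpGMatrix, mapping: pd.DataFrame, gene_set,
                      n_genes: int = 100, n_repeats: int = 100,
                      min_samples: int = 4, seed: int | None = None,
                      gene_set_label: str = "") -> CorrelationSummary:
    """Same procedure with the CpG -> gene assignment shuffled per repeat.

    The permutation is uniform over assignments within the selected set
    (the identity permutation is allowed).
    """
    groups = _gene_cpg_rows(mapping, gene_set)
    eligible = sorted(groups)
    if n_genes > len(eligible):
        raise ValueError(
            f"n_genes={n_genes} exceeds {len(eligible)} eligible genes")
    frac = matrix.fractions()
    rng = np.random.default_rng(seed)
    per_repeat = np.full(n_repeats, np.nan)
    pooled = []
    for rep in range(n_repeats):
        chosen = rng.choice(eligible, size=n_genes, replace=False)
        sizes = [len(groups[g]) for g in chosen]
        rows = np.concatenate([groups[g] for g in chosen])
        rows = rng.permutation(rows)
        r_all, _ = pairwise_correlations(frac[rows], min_samples)
        vals = []
        off = 0
        for sz in sizes:
            block = r_all[off:off + sz, off:off + sz]
            vals.append(block[np.triu_indices(sz, k=1)])
            off += sz
        vals = np.concatenate(vals)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            log.warning("null repeat %d: no eligible CpG pairs", rep)
            continue
        per_repeat[rep] = vals.mean()
        pooled.append(vals)
    return CorrelationSummary(
        mode="between_gene_null", gene_set_label=gene_set_label,
        per_repeat_mean=per_repeat,
        pooled=np.concatenate(pooled) if pooled else np.array([]),
        n_genes_per_repeat=n_genes, n_repeats=n_repeats, seed=seed,
        samples=list(matrix.samples))


def overlay_vs_null(within: CorrelationSummary,
                    null: CorrelationSummary) -> dict:
    """Empirical two-sided p for a single overlay mean against the null.

    For a small gene set (a population- or environment-specific overlay)
    the observed statistic is one within-gene mean over the whole set; its
    position in the Monte-Carlo null of per-repeat means gives an add-one
    empirical p.  Unlike a rank test over resampled repeats, this does not
    pseudo-replicate the observed side.
    """
    if within.samples != null.samples:
        raise ValueError("summaries come from different sample universes")
    obs = within.pooled_mean
    nulls = null.per_repeat_mean[np.isfinite(null.per_repeat_mean)]
    if len(nulls) == 0 or not np.isfinite(obs):
        raise ValueError("empty correlation summary")
    n = len(nulls)
    p_hi = (1 + np.sum(nulls >= obs)) / (n + 1)
    p_lo = (1 + np.sum(nulls <= obs)) / (n + 1)
    return {"observed_mean": float(obs), "null_mean": float(nulls.mean()),
            "effect": float(obs - nulls.mean()),
            "p": float(min(1.0, 2 * min(p_hi, p_lo))), "n_null": n}


def coordination_contrast(within: CorrelationSummary,
                          null: CorrelationSummary) -> dict:
    """Difference of pooled means plus a rank-sum test on per-repeat means."""
    if within.samples != null.samples:
        raise ValueError("summaries come from different sample universes")
    if len(within.pooled) == 0 or len(null.pooled) == 0:
        raise ValueError("empty correlation summary")
    a = within.per_repeat_mean[np.isfinite(within.per_repeat_mean)]
    b = null.per_repeat_mean[np.isfinite(null.per_repeat_mean)]
    stat, p = stats.ranksums(a, b)
    return {
        "effect": within.pooled_mean - null.pooled_mean,
        "within_mean": within.pooled_mean,
        "null_mean": null.pooled_mean,
        "p": float(p),
        "stat": float(stat),
        "n_repeats": (len(a), len(b)),
    }
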