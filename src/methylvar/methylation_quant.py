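"""Coverage filtering, CpG-to-gene assignment, and gene-level methylation.

The gene-level summary is the weighted methylation level W_gs: total
methylated reads over total reads across a gene's CpGs, per sample — a
coverage-weighted mean that down-weights poorly covered sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import CpGMatrix

log = logging.getLogger("methylvar")


@dataclass
class GeneMethylationTable:
    """Gene x sample weighted methylation with the underlying read sums.

    W = M / T where T > 0, NaN otherwise; n_cpgs counts CpGs with coverage
    passing the filter in that sample.
    """

    W: pd.DataFrame
    M: pd.DataFrame
    T: pd.DataFrame
    n_cpgs: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.W.index

    @property
    def samples(self) -> list[str]:
        return list(self.W.columns)

    def to_tsv(self, path) -> None:
        out = pd.concat({"W": self.W, "M": self.M, "T": self.T,
                         "n_cpgs": self.n_cpgs}, axis=1)
        out.columns = [f"{stat}_{s}" for stat, s in out.columns]
        out.to_csv(path, sep="\t", index_label="gene_id")


def filter_cpgs(matrix: CpGMatrix, min_cov: int = 10) -> CpGMatrix:
    """Mask (site, sample) cells with fewer than ``min_cov`` reads.

    Sites masked in every sample are dropped.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    out = matrix.copy()
    mask = out.total < min_cov
    out.meth[mask] = 0
    out.total[mask] = 0
    keep = (out.total > 0).any(axis=1)
    return CpGMatrix(out.sites.loc[keep], out.meth[keep], out.total[keep],
                     out.samples)


def assign_cpgs_to_features(matrix: CpGMatrix, genes: pd.DataFrame,
                            feature_class: str = "gene_body") -> pd.DataFrame:
    """Map CpGs onto gene features with bedtools-intersect semantics.

    A CpG at position p maps to a feature iff start <= p < end on the same
    contig; a CpG inside several overlapping features maps to all of them.
    Returns a frame with columns site_idx, gene_id.  CpGs absent from the
    frame are intergenic.
    """
    feats = genes
    if "feature_class" in genes.columns:
        feats = genes[genes["feature_class"] == feature_class]
    trees: dict[str, IntervalTree] = {}
    for contig, sub in feats.groupby("contig"):
        trees[contig] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"], sub["gene_id"]))
    rows = []
    for i, (contig, pos) in enumerate(zip(matrix.sites["contig"],
                                          matrix.sites["pos"])):
        tree = trees.get(contig)
        if tree is None:
            continue
        for iv in tree.at(pos):
            rows.append((i, iv.data))
    return pd.DataFrame(rows, columns=["site_idx", "gene_id"])


def intergenic_sites(matrix: CpGMatrix, mapping: pd.DataFrame) -> np.ndarray:
    """Indices of CpGs mapped to no feature."""
    mapped = np.zeros(matrix.n_sites, dtype=bool)
    mapped[mapping["site_idx"].to_numpy()] = True
    return np.flatnonzero(~mapped)


def weighted_gene_methylation(matrix: CpGMatrix,
                              mapping: pd.DataFrame) -> GeneMethylationTable:
    """Collapse CpGs within each gene to W_gs = sum(meth) / sum(total).

    Genes with zero assigned CpGs are absent from the table.  A gene whose
    CpGs are all masked in a sample has W missing there.
    """
    if mapping.empty:
        log.warning("no CpGs mapped to any gene")
        empty = pd.DataFrame(columns=matrix.samples)
        return GeneMethylationTable(empty, empty.copy(), empty.copy(),
                                    empty.copy())
    site_idx = mapping["site_idx"].to_numpy()
    gene_labels = mapping["gene_id"].to_numpy()
    genes, gene_codes = np.unique(gene_labels, return_inverse=True)
    n_g, n_s = len(genes), len(matrix.samples)
    M = np.zeros((n_g, n_s), dtype=np.int64)
    T = np.zeros_like(M)
    n_cpgs = np.zeros_like(M)
    np.add.at(M, gene_codes, matrix.meth[site_idx])
    np.add.at(T, gene_codes, matrix.total[site_idx])
    np.add.at(n_cpgs, gene_codes, (matrix.total[site_idx] > 0).astype(np.int64))
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(T > 0, M / T, np.nan)
    idx = pd.Index(genes, name="gene_id")
    cols = matrix.samples
    return GeneMethylationTable(
        pd.DataFrame(W, index=idx, columns=cols),
        pd.DataFrame(M, index=idx, columns=cols),
        pd.DataFrame(T, index=idx, columns=cols),
        pd.DataFrame(n_cpgs, index=idx, columns=cols),
    )


def cpg_binomial_call(meth, total, error_rate: float = 0.01):
    """One-sided upper-tail binomial p-value for a site being methylated.

    The null is the bisulfite non-conversion rate: observing ``meth`` or
    more methylated reads out of ``total`` by conversion error alone,
    p = P(X >= meth | n=total, p=error_rate).  Cells with total = 0 get NaN.
    """
    if not (0 < error_rate < 1):
        raise ValueError("error_rate must be in (0, 1)")
    meth = np.asarray(meth)
    total = np.asarray(total)
    if (meth < 0).any() or (meth > total).any():
        raise ValueError("require 0 <= meth <= total")
    with np.errstate(invalid="ignore"):
        p = stats.binom.sf(meth - 1, total, error_rate)
    p = np.where(total > 0, p, np.nan)
    if p.ndim == 0:
        return float(p)
    return p


def cpg_methylation_calls(matrix: CpGMatrix, error_rate: float = 0.01,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-CpG, per-sample methylation calls, BH-corrected within sample.

    Descriptive output: the gene-level analyses do not depend on it.
    """
    from .differential_methylation import bh_adjust

    p = cpg_binomial_call(matrix.meth, matrix.total, error_rate)
    q = np.full_like(p, np.nan, dtype=float)
    for j in range(len(matrix.samples)):
        obs = ~np.isnan(p[:, j])
        if obs.any():
            q[obs, j] = bh_adjust(p[obs, j])
    frames = matrix.sites.copy()
    for j, s in enumerate(matrix.samples):
        frames[f"p_{s}"] = p[:, j]
        frames[f"q_{s}"] = q[:, j]
        frames[f"call_{s}"] = q[:, j] < alpha
    return frames
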