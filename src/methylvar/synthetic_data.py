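"""Paired WGBS + RNA-seq simulator with known ground truth.

The generator emulates the evolve-and-resequence design the pipeline
analyses: two populations (FC / NC) assayed in native and reciprocal care
environments across replicate blocks, with WGBS libraries (3-4 per
condition) and RNA-seq libraries (11-12 per condition).

Methylomes are bimodal at the gene level: ~39% of genes are methylated,
with per-CpG latent fractions drawn from a high Beta component (default
Beta(9, 1)), while unmethylated genes sit at the bisulfite non-conversion
floor (Beta with mean = error_rate, default 1%).  Read coverage is
negative-binomial around 18x.  Planted population differences come in two
flavours: coordinated (one log-odds shift shared by every CpG of the
gene, random sign per gene) and sparse (a fraction of CpGs shifted with
independent random signs — no net gene-level change).  A small number of
genes are methylated in one population only.  Expression is
negative-binomial with log-normal gene means; methylated genes get higher
means and lower dispersion, the mechanism behind the reduced-variability
signal the pipeline is meant to recover.

One global seed fans out to per-stage child seeds so stages can be
regenerated independently and outputs are byte-identical under a seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CpGMatrix, validate_design, write_bed

log = logging.getLogger("methylvar")

CONDITIONS = (("FC", "FC"), ("FC", "NC"), ("NC", "NC"), ("NC", "FC"))


@dataclass
class SimConfig:
    """Study conditions for the simulator; defaults mirror the assayed design."""

    n_genes: int = 2000
    cpgs_per_gene: tuple[int, int] = (5, 25)
    n_intergenic_cpgs: int = 2000
    gene_length: int = 1000
    genes_per_contig: int = 200

    frac_methylated: float = 0.39
    n_fc_only: int = 32            # methylated in FC_POP only
    n_nc_only: int = 40            # methylated in NC_POP only
    meth_beta: tuple[float, float] = (9.0, 1.0)
    error_rate: float = 0.01       # non-conversion; unmethylated floor
    mean_coverage: float = 18.0
    coverage_dispersion: float = 10.0   # NB size; var = m + m^2/size

    n_dmg_coordinated: int = 60
    n_dmg_sparse: int = 60
    dmg_effect: float = 2.0        # log-odds shift in the NC population
    sparse_frac_cpgs: float = 0.2

    expr_log_mean: float = float(np.log(60.0))
    expr_log_sd: float = 1.3
    expr_meth_factor: float = 2.0  # mean multiplier for methylated genes
    dispersion_base: float = 0.2
    dispersion_multiplier_methylated: float = 0.5
    n_planted_deg: int = 60
    fold_change: float = 2.0
    size_factor_log_sd: float = 0.15

    n_divergent_snp_genes: int = 20

    wgbs_reps: tuple[int, int, int, int] = (4, 3, 4, 3)
    rna_reps: tuple[int, int, int, int] = (12, 11, 12, 11)
    n_blocks: int = 2

    def __post_init__(self) -> None:
        for frac in (self.frac_methylated, self.sparse_frac_cpgs,
                     self.error_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    @classmethod
    def scaled(cls, n_genes: int, **overrides) -> "SimConfig":
        """Config with planted-set sizes scaled proportionally to n_genes."""
        ref = cls()
        scale = n_genes / ref.n_genes
        counts = {f: max(0, round(getattr(ref, f) * scale))
                  for f in ("n_fc_only", "n_nc_only", "n_dmg_coordinated",
                            "n_dmg_sparse", "n_planted_deg",
                            "n_divergent_snp_genes", "n_intergenic_cpgs")}
        counts.update(overrides)
        return cls(n_genes=n_genes, **counts)


@dataclass
class TruthTables:
    """Planted ground truth, recorded before sampling noise is added."""

    methylated_fc: set = field(default_factory=set)
    methylated_nc: set = field(default_factory=set)
    dmg: pd.DataFrame = field(default_factory=pd.DataFrame)
    deg: pd.DataFrame = field(default_factory=pd.DataFrame)
    dispersion_multiplier: pd.DataFrame = field(default_factory=pd.DataFrame)
    divergent_genes: set = field(default_factory=set)

    @property
    def methylated_shared(self) -> set:
        return self.methylated_fc & self.methylated_nc

    def null_methylation_genes(self, universe) -> set:
        """Genes with no planted population difference in methylation."""
        planted = set(self.dmg["gene_id"]) if len(self.dmg) else set()
        planted |= self.methylated_fc ^ self.methylated_nc
        return set(universe) - planted


@dataclass
class SimulatedDataset:
    config: SimConfig
    seed: int
    genes: pd.DataFrame
    cpgs: pd.DataFrame          # contig, pos, strand, gene_id ('' intergenic)
    design: pd.DataFrame
    methylome: CpGMatrix
    counts: pd.DataFrame
    allele_freqs: pd.DataFrame
    truth: TruthTables


def make_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for assay, reps in (("WGBS", config.wgbs_reps), ("RNA", config.rna_reps)):
        for (pop, env), n in zip(CONDITIONS, reps):
            for i in range(n):
                rows.append({
                    "sample_id": f"{pop}pop_{env}env_{assay[0]}{i + 1}",
                    "population": pop,
                    "environment": env,
                    "block": (i % config.n_blocks) + 1,
                    "assay": assay,
                })
    return validate_design(pd.DataFrame(rows))


def generate_genome(config: SimConfig, seed) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping genes on synthetic contigs plus CpG coordinates."""
    rng = np.random.default_rng(seed)
    lo, hi = config.cpgs_per_gene
    if hi >= config.gene_length:
        raise ValueError("cannot pack more CpGs than gene positions")
    spacing = config.gene_length + 2500   # room for 1 kb upstream + gaps
    gene_rows, cpg_rows = [], []
    for g in range(config.n_genes):
        contig = f"scf{g // config.genes_per_contig + 1}"
        offset = (g % config.genes_per_contig) * spacing
        start = offset + 1500
        end = start + config.gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"g{g + 1:05d}"
        gene_rows.append((gene_id, contig, start, end, strand))
        n_cpg = int(rng.integers(lo, hi + 1))
        pos = np.sort(rng.choice(config.gene_length, size=n_cpg, replace=False))
        for p in pos:
            cpg_rows.append((contig, int(start + p), "+", gene_id))
    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "contig", "start", "end", "strand"])
    # intergenic CpGs: in the gap downstream of each gene body
    n_contigs = genes["contig"].nunique()
    for _ in range(config.n_intergenic_cpgs):
        g = int(rng.integers(config.n_genes))
        contig = genes.at[g, "contig"]
        gap_start = genes.at[g, "end"] + 50
        p = int(rng.integers(gap_start, gap_start + 1300))
        cpg_rows.append((contig, p, "+", ""))
    cpgs = (pd.DataFrame(cpg_rows, columns=["contig", "pos", "strand", "gene_id"])
            .drop_duplicates(["contig", "pos", "strand"])
            .sort_values(["contig", "pos", "strand"], kind="mergesort")
            .reset_index(drop=True))
    log.info("genome: %d genes on %d contigs, %d CpGs",
             len(genes), n_contigs, len(cpgs))
    return genes, cpgs


def _unmeth_beta(error_rate: float) -> tuple[float, float]:
    # Beta(1, b) with mean error_rate: the non-conversion noise floor
    return 1.0, 1.0 / error_rate - 1.0


def generate_methylomes(genes: pd.DataFrame, cpgs: pd.DataFrame,
                        config: SimConfig, design: pd.DataFrame,
                        seed) -> tuple[CpGMatrix, TruthTables]:
    rng = np.random.default_rng(seed)
    gene_ids = genes["gene_id"].to_numpy()
    n_genes = len(gene_ids)
    wgbs = design[design["assay"] == "WGBS"].reset_index(drop=True)
    if min(np.bincount(pd.factorize(
            wgbs["population"] + wgbs["environment"])[0])) < 3:
        raise ValueError("need >= 3 WGBS samples per condition")

    # --- methylation status truth ------------------------------------------
    n_meth = int(round(config.frac_methylated * n_genes))
    perm = rng.permutation(n_genes)
    shared_idx = perm[:n_meth]
    rest = perm[n_meth:]
    fc_only_idx = rest[:config.n_fc_only]
    nc_only_idx = rest[config.n_fc_only:config.n_fc_only + config.n_nc_only]
    status = {"FC": np.zeros(n_genes, dtype=bool),
              "NC": np.zeros(n_genes, dtype=bool)}
    for pop in ("FC", "NC"):
        status[pop][shared_idx] = True
    status["FC"][fc_only_idx] = True
    status["NC"][nc_only_idx] = True

    # --- per-CpG latent fractions ------------------------------------------
    cpg_gene = cpgs["gene_id"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    cpg_gidx = np.array([gene_pos.get(g, -1) for g in cpg_gene])
    n_cpgs = len(cpgs)
    a_m, b_m = config.meth_beta
    a_u, b_u = _unmeth_beta(config.error_rate)
    p_meth = rng.beta(a_m, b_m, size=n_cpgs)
    p_unmeth = rng.beta(a_u, b_u, size=n_cpgs)
    latent = {}
    for pop in ("FC", "NC"):
        meth_cpg = np.where(cpg_gidx >= 0, status[pop][cpg_gidx], False)
        latent[pop] = np.where(meth_cpg, p_meth, p_unmeth)

    # --- planted differential methylation (applied to the NC population) ---
    n_coord, n_sparse = config.n_dmg_coordinated, config.n_dmg_sparse
    pool = rng.permutation(shared_idx)
    if n_coord + n_sparse > len(pool):
        raise ValueError("too many planted DMGs for the methylated set")
    coord_idx = pool[:n_coord]
    sparse_idx = pool[n_coord:n_coord + n_sparse]
    dmg_rows = []
    logit_nc = np.log(latent["NC"] / (1 - latent["NC"]))
    for gi in coord_idx:
        direction = 1 if rng.random() < 0.5 else -1
        sel = cpg_gidx == gi
        logit_nc[sel] += direction * config.dmg_effect
        dmg_rows.append((gene_ids[gi], "coordinated", direction,
                         config.dmg_effect))
    for gi in sparse_idx:
        sel = np.flatnonzero(cpg_gidx == gi)
        n_shift = max(1, int(np.ceil(config.sparse_frac_cpgs * len(sel))))
        chosen = rng.choice(sel, size=n_shift, replace=False)
        signs = rng.choice([-1, 1], size=n_shift)
        logit_nc[chosen] += signs * config.dmg_effect
        dmg_rows.append((gene_ids[gi], "sparse", 0, config.dmg_effect))
    latent["NC"] = 1.0 / (1.0 + np.exp(-logit_nc))

    # --- reads ---------------------------------------------------------------
    size = config.coverage_dispersion
    p_nb = size / (size + config.mean_coverage)
    n_samples = len(wgbs)
    meth = np.empty((n_cpgs, n_samples), dtype=np.int64)
    total = np.empty_like(meth)
    for j, row in wgbs.iterrows():
        cov = rng.negative_binomial(size, p_nb, size=n_cpgs)
        meth[:, j] = rng.binomial(cov, latent[row["population"]])
        total[:, j] = cov
    matrix = CpGMatrix(cpgs[["contig", "pos", "strand"]].copy(), meth, total,
                       wgbs["sample_id"].tolist())

    truth = TruthTables(
        methylated_fc=set(gene_ids[status["FC"]]),
        methylated_nc=set(gene_ids[status["NC"]]),
        dmg=pd.DataFrame(dmg_rows,
                         columns=["gene_id", "mode", "direction", "effect"]),
    )
    return matrix, truth


def generate_expression(genes: pd.DataFrame, config: SimConfig,
                        design: pd.DataFrame, truth: TruthTables,
                        seed) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    gene_ids = genes["gene_id"].to_numpy()
    n_genes = len(gene_ids)
    rna = design[design["assay"] == "RNA"].reset_index(drop=True)
    if rna.empty:
        raise ValueError("design has no RNA samples")

    base = rng.lognormal(config.expr_log_mean, config.expr_log_sd, n_genes)
    meth = {pop: np.isin(gene_ids,
                         list(truth.methylated_fc if pop == "FC"
                              else truth.methylated_nc))
            for pop in ("FC", "NC")}
    mean_pop = {pop: base * np.where(meth[pop], config.expr_meth_factor, 1.0)
                for pop in ("FC", "NC")}
    disp_pop = {pop: config.dispersion_base
                * np.where(meth[pop], config.dispersion_multiplier_methylated, 1.0)
                for pop in ("FC", "NC")}

    deg_idx = rng.choice(n_genes, size=config.n_planted_deg, replace=False)
    deg_rows = []
    mean_pop["NC"] = mean_pop["NC"].copy()
    for gi in deg_idx:
        direction = 1 if rng.random() < 0.5 else -1
        mean_pop["NC"][gi] *= config.fold_change ** direction
        deg_rows.append((gene_ids[gi], direction,
                         direction * float(np.log2(config.fold_change))))

    factors = np.exp(rng.normal(0.0, config.size_factor_log_sd, len(rna)))
    counts = np.empty((n_genes, len(rna)), dtype=np.int64)
    for j, row in rna.iterrows():
        pop = row["population"]
        m = mean_pop[pop] * factors[j]
        disp = disp_pop[pop]
        size = np.where(disp > 0, 1.0 / np.clip(disp, 1e-12, None), 1e12)
        p_nb = size / (size + m)
        counts[:, j] = rng.negative_binomial(size, p_nb)

    truth.deg = pd.DataFrame(deg_rows,
                             columns=["gene_id", "direction", "log2fc"])
    truth.dispersion_multiplier = pd.DataFrame(
        {"FC": np.where(meth["FC"], config.dispersion_multiplier_methylated, 1.0),
         "NC": np.where(meth["NC"], config.dispersion_multiplier_methylated, 1.0)},
        index=pd.Index(gene_ids, name="gene_id"))
    return pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                        columns=rna["sample_id"].tolist())


def generate_allele_freqs(genes: pd.DataFrame, config: SimConfig,
                          seed) -> tuple[pd.DataFrame, set]:
    rng = np.random.default_rng(seed)
    gene_ids = genes["gene_id"].to_numpy()
    if config.n_divergent_snp_genes > len(gene_ids):
        raise ValueError("more divergent genes than genes")
    div_idx = set(rng.choice(len(gene_ids), size=config.n_divergent_snp_genes,
                             replace=False).tolist())
    rows = []
    snp = 0
    for i, g in enumerate(gene_ids):
        if i in div_idx:
            snp += 1
            hi_pop = rng.random() < 0.5
            f1, f2 = (0.9, 0.1) if hi_pop else (0.1, 0.9)
            rows.append((g, f"snp{snp}", f1, f2))
        n_bg = int(rng.integers(1, 4))
        for _ in range(n_bg):
            snp += 1
            rows.append((g, f"snp{snp}",
                         float(np.clip(rng.normal(0.5, 0.05), 0, 1)),
                         float(np.clip(rng.normal(0.5, 0.05), 0, 1))))
    freqs = pd.DataFrame(rows, columns=["gene_id", "snp_id",
                                        "freq_pop1", "freq_pop2"])
    return freqs, {gene_ids[i] for i in div_idx}


def generate_dataset(config: SimConfig | None = None,
                     seed: int = 0) -> SimulatedDataset:
    """Full paired dataset + truth tables under one global seed."""
    config = config or SimConfig()
    ss = np.random.SeedSequence(seed)
    s_genome, s_meth, s_expr, s_snp = ss.spawn(4)
    design = make_design(config)
    genes, cpgs = generate_genome(config, s_genome)
    methylome, truth = generate_methylomes(genes, cpgs, config, design, s_meth)
    counts = generate_expression(genes, config, design, truth, s_expr)
    allele_freqs, divergent = generate_allele_freqs(genes, config, s_snp)
    truth.divergent_genes = divergent
    return SimulatedDataset(config=config, seed=seed, genes=genes, cpgs=cpgs,
                            design=design, methylome=methylome, counts=counts,
                            allele_freqs=allele_freqs, truth=truth)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Emit the dataset as the standard text files the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    genes = ds.genes.copy()
    genes["feature_class"] = "gene_body"
    write_bed(genes, outdir / "genes.bed")
    ds.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    ds.allele_freqs.to_csv(outdir / "allele_freqs.tsv", sep="\t", index=False)
    frac = ds.methylome.fractions()
    for j, sample in enumerate(ds.methylome.samples):
        covered = ds.methylome.total[:, j] > 0
        cov = pd.DataFrame({
            "contig": ds.methylome.sites["contig"][covered],
            "start1": ds.methylome.sites["pos"][covered] + 1,
            "end1": ds.methylome.sites["pos"][covered] + 1,
            "pct": np.round(100 * frac[covered, j], 6),
            "count_meth": ds.methylome.meth[covered, j],
            "count_unmeth": (ds.methylome.total[covered, j]
                             - ds.methylome.meth[covered, j]),
        })
        cov.to_csv(outdir / f"{sample}.cov", sep="\t", index=False,
                   header=False)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    pd.Series(sorted(ds.truth.methylated_fc)).to_csv(
        truth_dir / "methylated_fc.txt", index=False, header=False)
    pd.Series(sorted(ds.truth.methylated_nc)).to_csv(
        truth_dir / "methylated_nc.txt", index=False, header=False)
    ds.truth.dmg.to_csv(truth_dir / "dmg.tsv", sep="\t", index=False)
    ds.truth.deg.to_csv(truth_dir / "deg.tsv", sep="\t", index=False)
    ds.truth.dispersion_multiplier.to_csv(
        truth_dir / "dispersion_multiplier.tsv", sep="\t")
    pd.Series(sorted(ds.truth.divergent_genes)).to_csv(
        truth_dir / "divergent_genes.txt", index=False, header=False)
    cfg = dataclasses.asdict(ds.config)
    pd.Series(cfg).to_csv(outdir / "sim_config.tsv", sep="\t", header=False)
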