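"""Orchestrate the analyses end to end and write a run report.

Three analyses, in dependency order: (1) gene-level differential
methylation with the shuffled-label empirical FDR; (2) methylation-status
classification (mixture and random-intercept routes) plus the
CpG-coordination resampling; (3) expression variability (CV2 loess
residuals) with gene-set comparisons, a minimal DE stage, and the shared
overlap/slope/SNP statistics.  In simulation mode, truth-recovery metrics
are appended.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cpg_coordination import (between_gene_null, coordination_contrast,
                               within_gene_pair_correlations)
from .differential_methylation import dmg_test, empirical_fdr
from .expression_variability import (compare_sets_variability,
                                     filter_low_expression, simple_de,
                                     variability_by_population)
from .io_formats import (CpGMatrix, merge_samples, read_counts,
                         read_cytosine_report, read_design,
                         read_gene_annotation)
from .methylation_quant import (assign_cpgs_to_features, filter_cpgs,
                                weighted_gene_methylation)
from .methylation_status import (call_methylated_genes_mixture,
                                 intercept_calls_per_population,
                                 methylated_set, population_specific_sets)
from .set_statistics import divergent_gene_set, fisher_overlap, slope_vs_one
from .synthetic_data import SimulatedDataset

log = logging.getLogger("methylvar")

#: (population, environment) pairs defining each side of the named contrasts
DEFAULT_CONTRASTS = {
    "environmental": ((("FC", "FC"),), (("FC", "NC"),)),
    "evolved": ((("FC", "FC"),), (("NC", "NC"),)),
    "reversal": ((("NC", "NC"),), (("NC", "FC"),)),
}


@dataclass
class RunConfig:
    """Thresholds and sizes for a full run; defaults follow the analysis."""

    min_cov: int = 10
    dmg_alpha: float = 0.01
    intercept_threshold: float = 2.5
    consistency: float = 0.85
    n_shuffles: int = 1000
    lfc_threshold: float = 1.0
    de_alpha: float = 0.05
    error_rate: float = 0.01
    loess_span: float = 0.75
    coord_n_genes: int = 100
    coord_n_repeats: int = 100
    coord_min_samples: int = 4
    seed: int = 0
    contrasts: dict = field(default_factory=lambda: dict(DEFAULT_CONTRASTS))


def _contrast_samples(design: pd.DataFrame, side, assay: str) -> list[str]:
    sub = design[design["assay"] == assay]
    keys = set(side)
    mask = [(p, e) in keys for p, e in zip(sub["population"],
                                           sub["environment"])]
    return sub.loc[mask, "sample_id"].tolist()


def validate_contrasts(design: pd.DataFrame, contrasts: dict,
                       assay: str = "WGBS") -> None:
    for name, (side1, side2) in contrasts.items():
        for side in (side1, side2):
            n = len(_contrast_samples(design, side, assay))
            if n < 2:
                raise ValueError(
                    f"contrast {name!r}: fewer than 2 {assay} samples on a side")


def load_inputs(coverage_paths: dict, annotation_path, counts_path,
                design_path) -> dict:
    """Read the on-disk inputs into the internal data model."""
    design = read_design(design_path)
    records = {s: read_cytosine_report(p, s) for s, p in coverage_paths.items()}
    matrix = merge_samples(records, design)
    genes = read_gene_annotation(annotation_path)
    counts = read_counts(counts_path)
    return {"design": design, "matrix": matrix, "genes": genes,
            "counts": counts}


def run_all(matrix: CpGMatrix, genes: pd.DataFrame, counts: pd.DataFrame,
            design: pd.DataFrame, config: RunConfig | None = None,
            allele_freqs: pd.DataFrame | None = None,
            truth=None, outdir: str | Path | None = None) -> dict:
    """Execute every stage and assemble the run report."""
    config = config or RunConfig()
    validate_contrasts(design, config.contrasts, "WGBS")
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {k: v for k, v in dataclasses.asdict(config).items()
                       if k != "contrasts"},
    }
    rng_children = np.random.SeedSequence(config.seed).spawn(4)

    # ---- stage 1: methylation quantification ------------------------------
    log.info("stage: methylation quantification")
    filtered = filter_cpgs(matrix, config.min_cov)
    mapping = assign_cpgs_to_features(filtered, genes)
    gmt = weighted_gene_methylation(filtered, mapping)
    report["methylation"] = {
        "n_cpgs_passing": int(filtered.n_sites),
        "n_genes_quantified": int(len(gmt.genes)),
    }

    # ---- stage 2: differential methylation + empirical FDR ----------------
    log.info("stage: differential methylation")
    report["dmg"] = {}
    dmg_tables = {}
    fdr_seeds = rng_children[0].spawn(len(config.contrasts))
    for (name, (side1, side2)), child in zip(config.contrasts.items(),
                                             fdr_seeds):
        s1 = _contrast_samples(design, side1, "WGBS")
        s2 = _contrast_samples(design, side2, "WGBS")
        cols = s1 + s2
        cond = np.array([0] * len(s1) + [1] * len(s2))
        block = design.set_index("sample_id").loc[cols, "block"].to_numpy()
        if len(np.unique(block)) < 2:
            block = None
        res = dmg_test(gmt.M[cols], gmt.T[cols], cond, block=block,
                       alpha=config.dmg_alpha)
        dmg_tables[name] = res
        fdr = empirical_fdr(gmt.M[cols], gmt.T[cols], cond, block=block,
                            n_shuffles=config.n_shuffles,
                            seed=int(child.generate_state(1)[0] % 2**31),
                            alpha=config.dmg_alpha)
        report["dmg"][name] = {
            "n_dmg": int(res["is_dmg"].sum()),
            "empirical_fdr": fdr.to_dict(),
        }

    # ---- stage 3: methylation status --------------------------------------
    log.info("stage: methylation status")
    mixture_calls = call_methylated_genes_mixture(
        gmt.W, consistency=config.consistency)
    intercept = intercept_calls_per_population(
        filtered, mapping, design, threshold=config.intercept_threshold)
    fc_set = methylated_set(intercept["FC"])
    nc_set = methylated_set(intercept["NC"])
    universe = set(gmt.genes)
    pop_sets = population_specific_sets(fc_set & universe, nc_set & universe,
                                        universe)
    report["status"] = {
        "n_methylated_mixture": int((mixture_calls["call"] == "methylated").sum()),
        "n_methylated_fc": len(fc_set),
        "n_methylated_nc": len(nc_set),
        "n_fc_only": len(pop_sets["FC_only"]),
        "n_nc_only": len(pop_sets["NC_only"]),
        "n_shared": len(pop_sets["shared"]),
    }

    # ---- stage 4: CpG coordination ----------------------------------------
    log.info("stage: CpG coordination")
    shared = pop_sets["shared"]
    coord_seed = int(rng_children[1].generate_state(1)[0] % 2**31)
    eligible = mapping[mapping["gene_id"].isin(shared)]
    n_elig = (eligible.groupby("gene_id").size() >= 2).sum()
    n_pick = min(config.coord_n_genes, int(n_elig))
    report["coordination"] = {}
    if n_pick >= 2:
        within = within_gene_pair_correlations(
            filtered, mapping, shared, n_genes=n_pick,
            n_repeats=config.coord_n_repeats,
            min_samples=config.coord_min_samples, seed=coord_seed,
            gene_set_label="methylated_shared")
        null = between_gene_null(
            filtered, mapping, shared, n_genes=n_pick,
            n_repeats=config.coord_n_repeats,
            min_samples=config.coord_min_samples, seed=coord_seed,
            gene_set_label="methylated_shared")
        report["coordination"]["shared"] = coordination_contrast(within, null)
        # overlays: whole-set mean of each population-specific set against
        # its shuffle null (the dotted-line-vs-null comparison)
        from .cpg_coordination import _gene_cpg_rows, overlay_vs_null
        for label in ("FC_only", "NC_only"):
            gene_set = pop_sets[label]
            n_set = len(_gene_cpg_rows(mapping, gene_set))
            if n_set < 2:
                continue
            w1 = within_gene_pair_correlations(
                filtered, mapping, gene_set, n_genes=n_set, n_repeats=1,
                min_samples=config.coord_min_samples, seed=coord_seed,
                gene_set_label=label)
            n_rep = between_gene_null(
                filtered, mapping, gene_set, n_genes=n_set,
                n_repeats=config.coord_n_repeats,
                min_samples=config.coord_min_samples, seed=coord_seed,
                gene_set_label=label)
            report["coordination"][f"overlay_{label}"] = \
                overlay_vs_null(w1, n_rep)

    # ---- stage 5: expression variability ----------------------------------
    log.info("stage: expression variability")
    counts_f = filter_low_expression(counts)
    vtab = variability_by_population(counts_f, design,
                                     span=config.loess_span)
    report["variability"] = {"n_genes_expressed": int(len(counts_f))}
    for pop in ("FC", "NC"):
        sub = vtab[vtab["population"] == pop]
        meth_here = (fc_set if pop == "FC" else nc_set) & set(sub.index)
        unmeth_here = set(sub.index) - (fc_set | nc_set)
        if len(meth_here) >= 3 and len(unmeth_here) >= 3:
            report["variability"][f"meth_vs_unmeth_{pop}"] = \
                compare_sets_variability(sub, meth_here, unmeth_here)
    fc_only_expr = pop_sets["FC_only"] & set(counts_f.index)
    unmeth_expr = pop_sets["neither"] & set(counts_f.index)
    if len(fc_only_expr) >= 3 and len(unmeth_expr) >= 3:
        report["variability"]["paired_fc_only"] = compare_sets_variability(
            vtab, fc_only_expr, unmeth_expr, paired=True)

    # ---- stage 6: differential expression + overlap statistics ------------
    log.info("stage: differential expression and set statistics")
    rna_env = {}
    for pop in ("FC", "NC"):
        sub = design[(design["assay"] == "RNA") & (design["population"] == pop)]
        cond = (sub["environment"] == "NC").astype(int).to_numpy()
        if len(np.unique(cond)) == 2:
            rna_env[pop] = simple_de(counts_f[sub["sample_id"].tolist()],
                                     cond, lfc_threshold=config.lfc_threshold,
                                     alpha=config.de_alpha)
    report["de"] = {pop: int(t["is_deg"].sum()) for pop, t in rna_env.items()}
    if len(rna_env) == 2:
        degs_fc = set(rna_env["FC"].index[rna_env["FC"]["is_deg"]])
        degs_nc = set(rna_env["NC"].index[rna_env["NC"]["is_deg"]])
        expr_universe = set(counts_f.index)
        if degs_fc and degs_nc:
            report["de"]["overlap"] = fisher_overlap(
                degs_fc, degs_nc, expr_universe).to_dict()
        both = sorted(degs_fc & degs_nc)
        if len(both) >= 3:
            sl = slope_vs_one(
                rna_env["FC"].loc[both, "log2fc"].to_numpy(),
                rna_env["NC"].loc[both, "log2fc"].to_numpy())
            if np.var(rna_env["FC"].loc[both, "log2fc"].to_numpy()) > 0:
                report["de"]["reaction_norm"] = dataclasses.asdict(sl)
    if allele_freqs is not None:
        divergent = divergent_gene_set(allele_freqs)
        report["snp"] = {"n_divergent": len(divergent)}
        meth_universe = universe
        if divergent & meth_universe and pop_sets["FC_only"] | pop_sets["NC_only"]:
            report["snp"]["divergence_vs_pop_specific"] = fisher_overlap(
                divergent & meth_universe,
                (pop_sets["FC_only"] | pop_sets["NC_only"]),
                meth_universe).to_dict()

    # ---- truth recovery (simulation mode) ---------------------------------
    if truth is not None:
        report["truth_recovery"] = truth_recovery_metrics(
            truth, universe, mixture_calls, fc_set, nc_set,
            dmg_tables.get("evolved"))

    if outdir is not None:
        _write_outputs(Path(outdir), report, gmt, dmg_tables, mixture_calls,
                       intercept, vtab, rna_env)
    return report


def truth_recovery_metrics(truth, universe: set, mixture_calls: pd.DataFrame,
                           fc_set: set, nc_set: set,
                           dmg_evolved: pd.DataFrame | None) -> dict:
    """Balanced accuracy of the classifiers and DMG sensitivity/FPR."""
    out = {}
    # the pooled mixture + consistency rule targets genes methylated across
    # (nearly) all samples, i.e. the planted shared set
    planted = truth.methylated_shared & universe
    mix_set = methylated_set(mixture_calls) & universe
    out["balanced_accuracy_mixture"] = balanced_accuracy(
        planted, mix_set, universe)
    out["balanced_accuracy_intercept_fc"] = balanced_accuracy(
        truth.methylated_fc & universe, fc_set & universe, universe)
    out["balanced_accuracy_intercept_nc"] = balanced_accuracy(
        truth.methylated_nc & universe, nc_set & universe, universe)
    if dmg_evolved is not None and len(truth.dmg):
        coord = set(truth.dmg.loc[truth.dmg["mode"] == "coordinated",
                                  "gene_id"]) & universe
        called = set(dmg_evolved.index[dmg_evolved["is_dmg"]])
        nulls = truth.null_methylation_genes(universe)
        out["dmg_sensitivity"] = (len(called & coord) / len(coord)
                                  if coord else np.nan)
        out["dmg_false_positive_rate"] = (len(called & nulls) / len(nulls)
                                          if nulls else np.nan)
    return out


def balanced_accuracy(true_set: set, called_set: set, universe: set) -> float:
    pos = true_set
    neg = universe - true_set
    if not pos or not neg:
        return float("nan")
    tpr = len(called_set & pos) / len(pos)
    tnr = len((universe - called_set) & neg) / len(neg)
    return float((tpr + tnr) / 2)


def run_simulated(sim: SimulatedDataset,
                  config: RunConfig | None = None,
                  outdir: str | Path | None = None) -> dict:
    """Run the full pipeline on a simulated dataset with truth recovery."""
    return run_all(sim.methylome, sim.genes, sim.counts, sim.design,
                   config=config, allele_freqs=sim.allele_freqs,
                   truth=sim.truth, outdir=outdir)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_outputs(outdir: Path, report: dict, gmt, dmg_tables,
                   mixture_calls, intercept, vtab, rna_env) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    gmt.to_tsv(outdir / "gene_methylation.tsv")
    for name, tab in dmg_tables.items():
        tab.to_csv(outdir / f"dmg_{name}.tsv", sep="\t")
    mixture_calls.to_csv(outdir / "status_mixture.tsv", sep="\t")
    for pop in ("FC", "NC"):
        if pop in intercept:
            intercept[pop].to_csv(outdir / f"status_intercept_{pop}.tsv",
                                  sep="\t")
    vtab.to_csv(outdir / "variability.tsv", sep="\t")
    for pop, tab in rna_env.items():
        tab.to_csv(outdir / f"de_{pop}.tsv", sep="\t")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    with open(outdir / "report.md", "w") as fh:
        fh.write(report_markdown(report))


def report_markdown(report: dict) -> str:
    lines = ["# methylvar run report", ""]

    def walk(d, depth=0):
        for k, v in d.items():
            if isinstance(v, dict):
                lines.append(f"{'  ' * depth}- **{k}**")
                walk(v, depth + 1)
            else:
                if isinstance(v, float):
                    v = f"{v:.6g}"
                elif isinstance(v, (list, np.ndarray)) and len(v) > 12:
                    v = f"[{len(v)} values]"
                lines.append(f"{'  ' * depth}- {k}: {v}")

    walk(report)
    return "\n".join(lines) + "\n"
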