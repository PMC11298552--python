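"""Readers and writers for the text formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). Bismark
inputs are 1-based and converted on read. Missing coverage is represented as
``total_reads == 0`` and surfaces as NaN methylation, never as methylation 0.
Gzip-compressed inputs are handled transparently by file extension.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("methylvar")

POPULATIONS = ("FC", "NC")
ENVIRONMENTS = ("FC", "NC")
ASSAYS = ("WGBS", "RNA")

SITE_COLUMNS = ["contig", "pos", "strand"]


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# CpGMatrix: the per-CpG x per-sample count container
# ---------------------------------------------------------------------------


@dataclass
class CpGMatrix:
    """Per-CpG methylated/total read counts across samples.

    ``sites`` holds one row per CpG (contig, pos, strand) in matrix row
    order; ``meth`` and ``total`` are (n_sites, n_samples) integer arrays.
    A cell with ``total == 0`` is missing (unobserved or masked).
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        self.samples = list(self.samples)
        if self.meth.shape != self.total.shape:
            raise ValueError("meth and total shapes differ")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count arrays do not match sites x samples")
        if (self.meth < 0).any() or (self.total < 0).any():
            raise ValueError("negative read counts")
        if (self.meth > self.total).any():
            raise ValueError("meth_reads exceeds total_reads")
        if self.sites.duplicated(SITE_COLUMNS).any():
            raise ValueError("duplicate (contig, pos, strand) sites")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def fractions(self) -> np.ndarray:
        """Methylation fractions, NaN where a cell has no coverage."""
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.meth / self.total
        return np.where(self.total > 0, frac, np.nan)

    def copy(self) -> "CpGMatrix":
        return CpGMatrix(self.sites.copy(), self.meth.copy(),
                         self.total.copy(), list(self.samples))

    def to_tsv(self, path: str | Path) -> None:
        out = self.sites.copy()
        for j, s in enumerate(self.samples):
            out[f"meth_{s}"] = self.meth[:, j]
            out[f"total_{s}"] = self.total[:, j]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CpGMatrix":
        df = pd.read_csv(path, sep="\t")
        samples = [c[len("meth_"):] for c in df.columns if c.startswith("meth_")]
        meth = df[[f"meth_{s}" for s in samples]].to_numpy(dtype=np.int64)
        total = df[[f"total_{s}" for s in samples]].to_numpy(dtype=np.int64)
        return cls(df[SITE_COLUMNS], meth, total, samples)


# ---------------------------------------------------------------------------
# Bismark-style per-CpG reports
# ---------------------------------------------------------------------------


def read_cytosine_report(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read one sample's Bismark coverage file or CX/cytosine report.

    Coverage dialect (6 columns): chrom, 1-based start, 1-based end,
    percent methylation, count methylated, count unmethylated.  The percent
    column is ignored and recomputed downstream from the counts.
    CX dialect (7 columns): chrom, 1-based pos, strand, count methylated,
    count unmethylated, context, trinucleotide; only CpG-context rows are
    kept.

    Returns a frame with columns contig, pos (0-based), strand, meth, total.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 6:
                    contig, start1, _end1, _pct, cm, cu = fields
                    strand = "+"
                elif len(fields) == 7:
                    contig, start1, strand, cm, cu, context, _tri = fields
                    if context.upper() not in ("CG", "CPG"):
                        continue
                    if strand not in ("+", "-"):
                        raise ValueError(f"bad strand {strand!r}")
                else:
                    raise ValueError(f"expected 6 or 7 columns, got {len(fields)}")
                pos = int(start1) - 1  # 1-based -> 0-based
                cm_i, cu_i = int(cm), int(cu)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: {exc}") from exc
            if cm_i < 0 or cu_i < 0:
                raise ValueError(
                    f"{path}: negative count at line {lineno}")
            rows.append((contig, pos, strand, cm_i, cm_i + cu_i))
    df = pd.DataFrame(rows, columns=["contig", "pos", "strand", "meth", "total"])
    df.attrs["sample_id"] = sample_id
    return df


def merge_samples(records: Mapping[str, pd.DataFrame],
                  design: pd.DataFrame) -> CpGMatrix:
    """Union per-sample CpG records into one matrix.

    Absent (site, sample) pairs get total_reads = 0.  Every WGBS sample in
    the design must be present in ``records``.
    """
    wgbs = design.loc[design["assay"] == "WGBS", "sample_id"].tolist()
    missing = [s for s in wgbs if s not in records]
    if missing:
        raise ValueError(f"samples in design missing from inputs: {missing}")
    frames = {}
    for s in wgbs:
        df = records[s]
        if df.duplicated(SITE_COLUMNS).any():
            raise ValueError(f"duplicate (site, sample) entries for sample {s}")
        frames[s] = df.set_index(SITE_COLUMNS)
    union = pd.Index([])
    for df in frames.values():
        union = union.union(df.index)
    sites = pd.DataFrame(list(union), columns=SITE_COLUMNS)
    sites = sites.sort_values(SITE_COLUMNS, kind="mergesort").reset_index(drop=True)
    idx = pd.MultiIndex.from_frame(sites)
    meth = np.zeros((len(sites), len(wgbs)), dtype=np.int64)
    total = np.zeros_like(meth)
    for j, s in enumerate(wgbs):
        aligned = frames[s].reindex(idx)
        meth[:, j] = aligned["meth"].fillna(0).to_numpy(dtype=np.int64)
        total[:, j] = aligned["total"].fillna(0).to_numpy(dtype=np.int64)
    return CpGMatrix(sites, meth, total, wgbs)


def merge_symmetric_strands(matrix: CpGMatrix) -> CpGMatrix:
    """Sum counts of +strand CpGs with the -strand C at pos+1.

    Off by default in the pipeline; symmetric CpG pairs are kept separate
    unless this is requested explicitly.
    """
    sites = matrix.sites
    plus = sites["strand"] == "+"
    key = pd.MultiIndex.from_arrays([
        sites["contig"],
        np.where(plus, sites["pos"], sites["pos"] - 1),
    ])
    out_sites = (pd.DataFrame({"contig": key.get_level_values(0),
                               "pos": key.get_level_values(1)})
                 .drop_duplicates().sort_values(["contig", "pos"])
                 .reset_index(drop=True))
    out_sites["strand"] = "+"
    lookup = {t: i for i, t in enumerate(zip(out_sites["contig"], out_sites["pos"]))}
    rows = np.array([lookup[t] for t in zip(key.get_level_values(0),
                                            key.get_level_values(1))])
    meth = np.zeros((len(out_sites), len(matrix.samples)), dtype=np.int64)
    total = np.zeros_like(meth)
    np.add.at(meth, rows, matrix.meth)
    np.add.at(total, rows, matrix.total)
    return CpGMatrix(out_sites, meth, total, matrix.samples)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "contig", "start", "end", "strand", "feature_class"]


def _parse_bed6(fh: IO[str]) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"BED line {lineno}: expected >=6 columns")
        contig, start, end, name, _score, strand = fields[:6]
        rows.append((name, contig, int(start), int(end), strand))
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])


def _parse_gff3(fh: IO[str]) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"GFF3 line {lineno}: expected 9 columns")
        contig, _src, ftype, start1, end1, _score, strand, _phase, attrs = fields
        if ftype != "gene":
            continue
        gene_id = None
        for item in attrs.split(";"):
            k, _, v = item.partition("=")
            if k.strip() in ("ID", "gene_id", "Name"):
                gene_id = v.strip()
                break
        if gene_id is None:
            raise ValueError(f"GFF3 line {lineno}: gene without ID attribute")
        rows.append((gene_id, contig, int(start1) - 1, int(end1), strand))
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])


def read_gene_annotation(path: str | Path,
                         contig_lengths: Mapping[str, int] | None = None,
                         upstream: int = 1000) -> pd.DataFrame:
    """Read BED6 or GFF3 gene models into gene_body + upstream_1kb records.

    One gene_body record per gene plus one upstream record spanning
    ``upstream`` bases 5' of the gene, truncated at contig boundaries.
    Genes whose id appears on more than one contig are dropped (count
    logged), mirroring annotations that exclude contig-split genes.
    """
    with _open_text(path) as fh:
        first = fh.readline()
        fh.seek(0)
        is_gff = first.startswith("##gff") or len(first.split("\t")) == 9
        genes = _parse_gff3(fh) if is_gff else _parse_bed6(fh)
    bad = genes[genes["end"] <= genes["start"]]
    if len(bad):
        raise ValueError(f"gene with end <= start: {bad['gene_id'].iloc[0]}")
    n_contigs = genes.groupby("gene_id")["contig"].nunique()
    split = n_contigs[n_contigs > 1].index
    if len(split):
        log.warning("dropping %d genes split across multiple contigs", len(split))
        genes = genes[~genes["gene_id"].isin(split)]
    genes = genes.reset_index(drop=True)

    body = genes.copy()
    body["feature_class"] = "gene_body"
    up = genes.copy()
    plus = up["strand"] == "+"
    up_start = np.where(plus, up["start"] - upstream, up["end"])
    up_end = np.where(plus, up["start"], up["end"] + upstream)
    up_start = np.maximum(up_start, 0)
    if contig_lengths is not None:
        lens = up["contig"].map(contig_lengths)
        if lens.notna().all():
            up_end = np.minimum(up_end, lens.to_numpy(dtype=np.int64))
    up["start"], up["end"] = up_start, up_end
    up["feature_class"] = "upstream_1kb"
    up = up[up["end"] > up["start"]]
    out = pd.concat([body, up], ignore_index=True)
    return out[GENE_COLUMNS]


# ---------------------------------------------------------------------------
# Design and count tables
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> pd.DataFrame:
    """Design TSV with header sample_id, population, environment, block, assay."""
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_design(design)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    required = ["sample_id", "population", "environment", "block", "assay"]
    missing = [c for c in required if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design")
    for col, allowed in (("population", POPULATIONS),
                         ("environment", ENVIRONMENTS),
                         ("assay", ASSAYS)):
        bad = set(design[col]) - set(allowed)
        if bad:
            raise ValueError(f"invalid {col} values: {sorted(bad)}")
    design = design.copy()
    design["block"] = design["block"].astype(int)
    return design


def read_counts(path: str | Path) -> pd.DataFrame:
    """RNA-seq raw count TSV: first column gene_id, remaining sample columns."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts < 0).any().any():
        raise ValueError("negative counts")
    return counts.astype(np.int64)


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    body = genes[genes["feature_class"] == "gene_body"] \
        if "feature_class" in genes.columns else genes
    out = body[["contig", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = body["strand"].to_numpy()
    out.to_csv(path, sep="\t", index=False, header=False)
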