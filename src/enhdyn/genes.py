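"""Enhancer-to-gene assignment and expression gene sets.

Each peak is linked to the single nearest transcription start site within
a distance window (25 kb or 200 kb by default), distances being measured
from the peak midpoint; strand enters only through which end of the gene
span is the TSS.  Differential-expression tables (gene, baseMean, log2FC,
adjusted p) are inputs, not fitted here.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from pathlib import Path
import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .intervals import GenomicInterval, PeakAtlas

__all__ = [
    "read_gene_annotation",
    "nearest_tss_assignment",
    "filter_de_genes",
    "read_de_table",
    "cluster_expression_patterns",
    "filter_promoter_distal",
]

WINDOWS = (25_000, 200_000)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, chrom, start, end, strand).

    Returns a DataFrame indexed by gene_id with columns chrom, tss, strand.
    The TSS is the start for '+' genes and end-1 for '-' genes (0-based).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=["gene_id", "chrom", "start", "end", "strand"],
        header=None,
        comment="#",
    )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    tss = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    out = pd.DataFrame(
        {"chrom": df["chrom"].to_numpy(), "tss": tss, "strand": df["strand"].to_numpy()},
        index=pd.Index(df["gene_id"], name="gene_id"),
    )
    if (out["tss"] < 0).any():
        raise ValueError("negative TSS coordinate")
    return out


def nearest_tss_assignment(
    peaks: PeakAtlas, genes: pd.DataFrame, window: int
) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS within ``window`` bp.

    ``genes`` is a DataFrame indexed by gene_id with columns chrom and tss.
    Distance = |peak midpoint - TSS|.  Peaks whose nearest TSS is farther
    than ``window`` are left out.  Equidistant TSS ties go to the
    lexicographically smaller gene_id (deterministic; a warning is emitted).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    rows = []
    by_chrom: dict[str, tuple[list[int], list[str]]] = {}
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("tss", kind="stable")
        by_chrom[str(chrom)] = (sub["tss"].tolist(), sub.index.tolist())
    n_ties = 0
    for iv in peaks:
        if iv.chrom not in by_chrom:
            continue
        tss_list, ids = by_chrom[iv.chrom]
        mid = iv.midpoint
        j = bisect_left(tss_list, mid)
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < len(tss_list):
                d = abs(tss_list[cand] - mid)
                if best is None or d < best:
                    best = d
        if best is None or best > window:
            continue
        lo = bisect_left(tss_list, mid - best)
        hi = bisect_right(tss_list, mid + best)
        candidates = sorted(ids[lo:hi])
        if len(candidates) > 1:
            n_ties += 1
        rows.append((iv.name, candidates[0], best, window))
    if n_ties:
        warnings.warn(f"{n_ties} peaks had equidistant TSS ties; "
                      "lexicographically smaller gene_id chosen")
    return pd.DataFrame(rows, columns=["peak", "gene_id", "distance", "window"])


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV with header
    (gene, baseMean, log2FoldChange, padj); indexed by gene."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "baseMean", "log2FoldChange", "padj"}
    if not required.issubset(df.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    return df.set_index("gene")


def filter_de_genes(
    table: pd.DataFrame,
    base_mean_min: float = 1000.0,
    lfc_min: float = 1.5,
    padj_max: float = 0.05,
    direction: str = "up",
) -> set[str]:
    """Thresholded differential-expression gene set.

    up:   baseMean > base_mean_min AND log2FC >  lfc_min AND padj < padj_max
    down: baseMean > base_mean_min AND log2FC < -lfc_min AND padj < padj_max
    Genes with missing padj are excluded.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    lfc = table["log2FoldChange"]
    keep = (
        (table["baseMean"] > base_mean_min)
        & table["padj"].notna()
        & (table["padj"] < padj_max)
    )
    keep &= (lfc > lfc_min) if direction == "up" else (lfc < -lfc_min)
    return set(table.index[keep])


def cluster_expression_patterns(expr: pd.DataFrame, k: int = 10) -> pd.Series:
    """Group gene-expression patterns by agglomerative clustering.

    Rows (genes) are z-scored across conditions, then clustered with
    average-linkage Euclidean agglomeration cut at ``k`` clusters.
    Constant rows carry no pattern and are set aside in a dedicated
    ``flat`` cluster.  Labels are ``C01``..``Ck`` plus ``flat``;
    deterministic for a given input.
    """
    vals = expr.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    flat = (sd <= 1e-12).ravel()
    labels = pd.Series(index=expr.index, dtype=object)
    labels[flat] = "flat"
    z = (vals[~flat] - mu[~flat]) / sd[~flat]
    n = z.shape[0]
    if n:
        k_eff = min(k, n)
        if k_eff == n:
            assign = np.arange(n)
        else:
            model = AgglomerativeClustering(
                n_clusters=k_eff, linkage="average", metric="euclidean"
            )
            assign = model.fit_predict(z)
        labels[~flat] = [f"C{c + 1:02d}" for c in assign]
    if n and n < k:
        warnings.warn(f"only {n} non-flat genes for k={k}; one cluster per gene")
    return labels


def filter_promoter_distal(
    peaks: PeakAtlas, genes: pd.DataFrame, tss_window: int = 2000
) -> PeakAtlas:
    """Drop peaks whose midpoint lies within ±tss_window of any TSS.

    The remaining promoter-distal peaks are the putative enhancers used for
    temporal clustering.
    """
    by_chrom: dict[str, list[int]] = {
        str(c): sorted(sub["tss"].tolist()) for c, sub in genes.groupby("chrom")
    }
    kept: list[GenomicInterval] = []
    for iv in peaks:
        tss_list = by_chrom.get(iv.chrom)
        if tss_list:
            mid = iv.midpoint
            j = bisect_left(tss_list, mid)
            near = min(
                (abs(tss_list[c] - mid) for c in (j - 1, j) if 0 <= c < len(tss_list)),
                default=None,
            )
            if near is not None and near <= tss_window:
                continue
        kept.append(iv)
    return PeakAtlas(kept, peaks.genome_label, presorted=True)
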