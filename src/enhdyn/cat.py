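"""Bootstrap cluster alignment between two clustered single-cell datasets.

For every cluster, the mean expression profile over a shared gene panel
is bootstrap-resampled (cells drawn with replacement, 1,000 replicates by
default).  A source cluster is compared to each target cluster by the
Euclidean distance from its bootstrap means to the target's bootstrap
centroid, giving a distance distribution per target.  The nearest target
is the one with the smallest mean distance; an alignment is declared
significant when the nearest distance distribution separates from the
next-ranked one by more than a scale-free margin (one-sided Welch test).
Alignment is directional; mutual nearest pairs are flagged.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellMatrix",
    "qc_filter_cells",
    "lognormalize",
    "scale_cells",
    "highly_variable_panel",
    "BootstrapProfiles",
    "bootstrap_cluster_profiles",
    "align_clusters",
]


@dataclass
class CellMatrix:
    """Cell x gene UMI counts plus per-cell metadata.

    ``meta`` is indexed like the count rows and must carry a ``cluster``
    column; ``mito_fraction`` is taken from ``meta`` if present, otherwise
    computed from genes whose name starts with ``mito_prefix``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            self.meta = self.meta.loc[self.counts.index]
        if (self.counts.values < 0).any():
            raise ValueError("UMI counts must be non-negative")

    @property
    def total_umis(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def detected_genes(self) -> pd.Series:
        return (self.counts > 0).sum(axis=1)

    @property
    def mito_fraction(self) -> pd.Series:
        if "mito_fraction" in self.meta.columns:
            return self.meta["mito_fraction"]
        mito = [g for g in self.counts.columns if str(g).startswith(self.mito_prefix)]
        tot = self.total_umis
        if not mito:
            return pd.Series(0.0, index=self.counts.index)
        return self.counts[mito].sum(axis=1) / tot.where(tot > 0, 1)

    def subset(self, cells: pd.Index) -> "CellMatrix":
        return CellMatrix(self.counts.loc[cells], self.meta.loc[cells], self.mito_prefix)


def qc_filter_cells(
    m: CellMatrix,
    umi_bounds: tuple[float, float] = (2_000, 35_000),
    gene_bounds: tuple[float, float] = (550, 4_950),
    mito_max: float = 0.20,
) -> tuple[CellMatrix, dict[str, int]]:
    """Remove low-quality cells by UMI count, detected genes and mito content.

    Cells are kept when total UMIs and detected genes lie strictly inside
    their (lower, upper) bounds and the mitochondrial fraction does not
    exceed ``mito_max``.  Returns the filtered matrix and a per-criterion
    removal log (a cell may count toward several criteria).
    """
    for lo, hi in (umi_bounds, gene_bounds):
        if not lo < hi:
            raise ValueError("bounds must satisfy lower < upper")
    umis = m.total_umis
    genes = m.detected_genes
    mito = m.mito_fraction
    ok_umi = (umis > umi_bounds[0]) & (umis < umi_bounds[1])
    ok_gene = (genes > gene_bounds[0]) & (genes < gene_bounds[1])
    ok_mito = mito <= mito_max
    keep = ok_umi & ok_gene & ok_mito
    log = {
        "input_cells": len(keep),
        "removed_umi": int((~ok_umi).sum()),
        "removed_genes": int((~ok_gene).sum()),
        "removed_mito": int((~ok_mito).sum()),
        "kept": int(keep.sum()),
    }
    if log["kept"] == 0:
        raise ValueError(
            "QC removed every cell; review the UMI/gene/mito thresholds "
            f"(log: {log})"
        )
    return m.subset(m.counts.index[keep]), log


def lognormalize(m: CellMatrix, scale: float = 10_000.0) -> pd.DataFrame:
    """Library-size log-normalisation: ln(1 + scale * count / cell_total)."""
    totals = m.total_umis
    if (totals <= 0).any():
        raise ValueError("zero-total cells present; run QC filtering first")
    frac = m.counts.div(totals, axis=0) * scale
    return np.log1p(frac)


def scale_cells(normalized: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene across cells (removes platform scale).

    Genes whose between-cluster differences are small relative to the
    cell-to-cell spread end up with near-zero scaled cluster contrasts,
    so they contribute little to cross-dataset distances; invariant genes
    become all-zero columns.
    """
    mu = normalized.mean(axis=0)
    sd = normalized.std(axis=0, ddof=0)
    return (normalized - mu).div(sd.where(sd > 1e-12, 1.0), axis=1)


def highly_variable_panel(
    a: pd.DataFrame, b: pd.DataFrame, n_top: int = 2_000
) -> list[str]:
    """Shared gene panel: union of each dataset's top variance genes
    (log-normalised), intersected with the genes present in both."""
    shared = [g for g in a.columns if g in set(b.columns)]
    panel: set[str] = set()
    for df in (a, b):
        var = df[shared].var(axis=0)
        panel |= set(var.sort_values(ascending=False).index[:n_top])
    return [g for g in shared if g in panel]


@dataclass
class BootstrapProfiles:
    """Per-cluster bootstrap replicate mean-expression vectors."""

    profiles: dict[str, np.ndarray]  # cluster -> (n_boot, n_panel)
    gene_panel: list[str]
    n_boot: int
    seed: int
    excluded: list[str] = field(default_factory=list)

    def clusters(self) -> list[str]:
        return list(self.profiles)

    def centroids(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: p.mean(axis=0) for c, p in self.profiles.items()},
            index=self.gene_panel,
        ).T


def _cluster_rng(seed: int, cluster: str) -> np.random.Generator:
    # independent, name-keyed stream per cluster: stable regardless of
    # iteration order or how many clusters exist
    return np.random.default_rng([seed, zlib.crc32(str(cluster).encode())])


def bootstrap_cluster_profiles(
    normalized: pd.DataFrame,
    labels: pd.Series,
    gene_panel: Sequence[str],
    n_boot: int = 1_000,
    seed: int = 0,
    min_cells: int = 2,
) -> BootstrapProfiles:
    """Bootstrap the per-cluster mean expression over ``gene_panel``.

    Each replicate resamples the cluster's cells with replacement and
    averages their normalised expression.  Streams are seeded per cluster
    name, so results are bitwise-reproducible and independent of cluster
    iteration order.  Clusters below ``min_cells`` are excluded.
    """
    panel = list(gene_panel)
    x = normalized[panel]
    profiles: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for cluster in sorted(labels.dropna().unique(), key=str):
        cells = labels.index[labels == cluster]
        if len(cells) < min_cells:
            warnings.warn(f"cluster {cluster!r} has <{min_cells} cells; excluded")
            excluded.append(str(cluster))
            continue
        sub = x.loc[cells].to_numpy()
        rng = _cluster_rng(seed, str(cluster))
        idx = rng.integers(0, len(cells), size=(n_boot, len(cells)))
        # mean over resampled cells, all replicates at once
        profiles[str(cluster)] = sub[idx].mean(axis=1)
    return BootstrapProfiles(profiles, panel, n_boot, seed, excluded)


def _zscore_profiles(p: BootstrapProfiles) -> dict[str, np.ndarray]:
    """Z-score panel genes using the pooled centroid mean/sd of the dataset
    (removes platform scale before cross-dataset distances)."""
    cent = np.stack([arr.mean(axis=0) for arr in p.profiles.values()])
    mu = cent.mean(axis=0)
    sd = cent.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return {c: (arr - mu) / sd for c, arr in p.profiles.items()}


def align_clusters(
    a: BootstrapProfiles,
    b: BootstrapProfiles,
    alpha: float = 0.01,
    effect_margin: float | str = "auto",
    rank_depth: int = 2,
    zscore: bool = False,
) -> pd.DataFrame:
    """Directional alignment of clusters in ``a`` onto clusters in ``b``.

    For each source cluster the Euclidean distances from its bootstrap
    means to every target centroid form per-target distributions.  Ranks
    are by mean distance.  The alignment extends to rank r (up to
    ``rank_depth``) when the rank-r distances separate from rank r+1 by
    more than ``effect_margin`` (one-sided Welch test at ``alpha``); with
    ``effect_margin="auto"`` the margin is 0.25 x the median inter-cluster
    mean distance, a scale-free gap requirement that keeps tightly
    clustered but unrelated targets from producing spurious alignments.

    Returns a long DataFrame (source, target, rank, mean_distance,
    distance_sd, p_separation, significant, mutual_nearest) plus the
    criterion metadata in ``DataFrame.attrs``.
    """
    if a.gene_panel != b.gene_panel:
        raise ValueError("gene panels differ between the two profile sets")
    # profiles are normally built on cell-scaled expression (scale_cells);
    # zscore=True additionally standardises panel genes across centroids
    pa = _zscore_profiles(a) if zscore else dict(a.profiles)
    pb = _zscore_profiles(b) if zscore else dict(b.profiles)
    b_centroids = {c: arr.mean(axis=0) for c, arr in pb.items()}
    targets = list(b_centroids)

    dist: dict[str, pd.DataFrame] = {}
    for src, boots in pa.items():
        d = {t: np.linalg.norm(boots - b_centroids[t][None, :], axis=1) for t in targets}
        dist[src] = pd.DataFrame(d)

    mean_table = pd.DataFrame(
        {src: df.mean(axis=0) for src, df in dist.items()}
    ).T  # source x target
    if effect_margin == "auto":
        margin = 0.25 * float(np.median(mean_table.to_numpy()))
    else:
        margin = float(effect_margin)

    # reverse nearest map for mutual-nearest flags
    rev_nearest: dict[str, str] = {}
    a_centroids = {c: arr.mean(axis=0) for c, arr in pa.items()}
    for src_b, boots in pb.items():
        dmeans = {
            t: float(np.linalg.norm(boots - a_centroids[t][None, :], axis=1).mean())
            for t in a_centroids
        }
        rev_nearest[src_b] = min(dmeans, key=lambda t: (dmeans[t], t))

    rows = []
    for src, df in dist.items():
        order = mean_table.loc[src].sort_values(kind="stable").index.tolist()
        n_targets = len(order)
        # deepest rank whose separation from the next rank is significant
        sig_rank = 0
        p_by_rank: dict[int, float] = {}
        for r in range(1, min(rank_depth, n_targets - 1) + 1):
            d_r = df[order[r - 1]].to_numpy()
            d_next = df[order[r]].to_numpy()
            p_by_rank[r] = _welch_one_sided(d_next, d_r, margin)
            if p_by_rank[r] < alpha:
                sig_rank = r
                break
        for r, tgt in enumerate(order[: max(rank_depth, 1)], start=1):
            if r > min(rank_depth, n_targets):
                break
            rows.append(
                {
                    "source": src,
                    "target": tgt,
                    "rank": r,
                    "mean_distance": float(df[tgt].mean()),
                    "distance_sd": float(df[tgt].std(ddof=1)),
                    "p_separation": p_by_rank.get(r, float("nan")),
                    "significant": bool(n_targets >= 2 and sig_rank >= r),
                    "mutual_nearest": bool(r == 1 and rev_nearest.get(tgt) == src),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["criterion"] = {
        "alpha": alpha,
        "effect_margin": margin,
        "rank_depth": rank_depth,
        "zscore": zscore,
        "n_boot": a.n_boot,
    }
    return out


def _welch_one_sided(d_far: np.ndarray, d_near: np.ndarray, margin: float) -> float:
    """One-sided Welch p for mean(d_far) - mean(d_near) > margin."""
    n1, n2 = len(d_far), len(d_near)
    m = d_far.mean() - d_near.mean() - margin
    v1, v2 = d_far.var(ddof=1), d_near.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 <= 0:
        return 0.0 if m > 0 else 1.0
    t = m / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    return float(stats.t.sf(t, df))
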