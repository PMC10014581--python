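"""Observed/expected enrichment of enhancer classes against gene sets and
tissue H3K27ac region sets, with chi-squared significance.

The statistic is the log2 ratio of the observed count of class members
hitting a set to the count expected under independence, where "expected"
is the two-way contingency expectation (row total x column total / grand
total).  Significance comes from the 1-df chi-squared test on the 2x2
table (class vs rest) x (in-set vs not), without continuity correction; a
label-permutation p-value is available as a small-count cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import (
    PeakAtlas,
    intersect,
    intersect_any,
    reproducible_peaks,
    union_atlas,
)

__all__ = [
    "chi2_2x2",
    "enrichment_row",
    "class_geneset_enrichment",
    "permutation_pvalue",
    "TissueRegionSets",
    "build_tissue_sets",
    "class_region_enrichment",
    "TISSUE_ORDER",
    "LINEAGE_MAP",
]

#: Fixed tissue axis order for output tables (radar-chart order).
TISSUE_ORDER = (
    "pancreas",
    "liver",
    "heart",
    "adrenal",
    "brain",
    "RPE",
    "lung",
    "stomach",
)

#: Germ-layer membership of the foetal tissues.
LINEAGE_MAP = {
    "RPE": "ectoderm",
    "brain": "ectoderm",
    "pancreas": "endoderm",
    "liver": "endoderm",
    "lung": "endoderm",
    "stomach": "endoderm",
    "heart": "mesoderm",
    "adrenal": "mesoderm",
}


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, 1 df, no continuity correction.

    Returns (nan, nan) when any marginal is zero (the expectation is then
    degenerate).
    """
    from scipy import stats

    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    if n <= 0 or (rows == 0).any() or (cols == 0).any():
        return float("nan"), float("nan")
    expected = np.outer(rows, cols) / n
    chi2 = float(((t - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))


def enrichment_row(
    class_name: str,
    set_name: str,
    observed: int,
    n_class: int,
    in_set_total: int,
    grand_total: int,
) -> dict:
    """One enrichment record from 2x2 marginals.

    expected = n_class * in_set_total / grand_total.  observed == 0 yields a
    -inf score flagged as censored; expected == 0 yields a missing record.
    """
    if grand_total == 0 or in_set_total == 0:
        return {
            "class": class_name,
            "set": set_name,
            "observed": observed,
            "expected": np.nan,
            "score": np.nan,
            "chi2": np.nan,
            "pvalue": np.nan,
            "censored": True,
        }
    expected = n_class * in_set_total / grand_total
    score = float(np.log2(observed / expected)) if observed > 0 else -np.inf
    table = np.array(
        [
            [observed, n_class - observed],
            [in_set_total - observed, (grand_total - n_class) - (in_set_total - observed)],
        ]
    )
    chi2, pvalue = chi2_2x2(table)
    return {
        "class": class_name,
        "set": set_name,
        "observed": observed,
        "expected": expected,
        "score": score,
        "chi2": chi2,
        "pvalue": pvalue,
        "censored": observed == 0,
    }


def class_geneset_enrichment(
    links: pd.DataFrame,
    class_labels: pd.Series,
    gene_set: Iterable[str],
    set_name: str = "gene_set",
) -> pd.DataFrame:
    """Enrichment of each enhancer class in a differential-expression gene set.

    ``links`` is the peak->gene table (columns peak, gene_id); only peaks
    carrying a class label and a link enter the universe.  For class c:
    observed = number of class-c linked peaks whose gene is in the set;
    expected = n_c * (total in-set-linked / total linked).
    """
    gene_set = set(gene_set)
    lab = class_labels.dropna()
    tab = links[["peak", "gene_id"]].copy()
    tab["class"] = tab["peak"].map(lab)
    tab = tab.dropna(subset=["class"])
    tab = tab.drop_duplicates(subset="peak")
    tab["in_set"] = tab["gene_id"].isin(gene_set)
    grand_total = len(tab)
    in_set_total = int(tab["in_set"].sum())
    rows = []
    for cls, sub in tab.groupby("class", sort=True):
        rows.append(
            enrichment_row(
                str(cls),
                set_name,
                int(sub["in_set"].sum()),
                len(sub),
                in_set_total,
                grand_total,
            )
        )
    out = pd.DataFrame(rows)
    if len(out):
        obs_sum = out["observed"].sum()
        assert obs_sum == in_set_total, "class observed counts must sum to the column total"
    return out


def permutation_pvalue(
    links: pd.DataFrame,
    class_labels: pd.Series,
    gene_set: Iterable[str],
    class_name: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """One-sided label-permutation p for over-representation of one class.

    Shuffles peak->class labels ``n_perm`` times and counts how often the
    permuted in-set count reaches the observed one (add-one estimator).
    """
    gene_set = set(gene_set)
    lab = class_labels.dropna()
    tab = links[["peak", "gene_id"]].drop_duplicates(subset="peak")
    tab = tab[tab["peak"].isin(lab.index)]
    in_set = tab["gene_id"].isin(gene_set).to_numpy()
    labels = tab["peak"].map(lab).to_numpy()
    observed = int(in_set[labels == class_name].sum())
    rng = np.random.default_rng(seed)
    n_class = int((labels == class_name).sum())
    hits = 0
    for _ in range(n_perm):
        perm_idx = rng.choice(len(labels), size=n_class, replace=False)
        if int(in_set[perm_idx].sum()) >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Tissue H3K27ac sets
# ---------------------------------------------------------------------------


@dataclass
class TissueRegionSets:
    """Replicate-consistent, tissue-unique and lineage-unique H3K27ac sets."""

    consistent: dict[str, PeakAtlas]
    tissue_unique: dict[str, PeakAtlas]
    lineage: dict[str, PeakAtlas]
    lineage_unique: dict[str, PeakAtlas]
    single_replicate_tissues: list[str] = field(default_factory=list)

    def region_sets(self) -> dict[str, PeakAtlas]:
        """Flat mapping of every named set (tissue-unique then lineage-unique)."""
        out = {t: self.tissue_unique[t] for t in self.tissue_unique}
        out.update({f"{l}-unique": a for l, a in self.lineage_unique.items()})
        return out


def build_tissue_sets(
    replicate_peaks: Mapping[str, tuple[PeakAtlas, ...]],
    lineage_map: Mapping[str, str] | None = None,
    min_frac: float = 0.5,
) -> TissueRegionSets:
    """Construct tissue and germ-layer region sets from replicate peak calls.

    Replicate-consistent peaks pass the reciprocal-fraction filter
    (``-f 0.50 -r -u``); tissues with a single replicate pass through
    unfiltered with a warning.  A tissue-unique region overlaps no other
    tissue's consistent set; lineage-unique sets are built the same way on
    the concatenated per-layer sets.  Unique sets are sorted and merged so
    each regulatory region is counted once.
    """
    if lineage_map is None:
        lineage_map = LINEAGE_MAP
    if not replicate_peaks:
        raise ValueError("need at least one tissue")
    missing = [t for t in replicate_peaks if t not in lineage_map]
    if missing:
        raise ValueError(f"tissues missing from lineage map: {missing}")

    consistent: dict[str, PeakAtlas] = {}
    singles: list[str] = []
    for tissue, reps in replicate_peaks.items():
        if len(reps) == 1:
            warnings.warn(f"tissue {tissue!r} has a single replicate; "
                          "peaks pass through unfiltered")
            consistent[tissue] = reps[0]
            singles.append(tissue)
        else:
            consistent[tissue] = reproducible_peaks(
                reps[0], reps[1], min_frac=min_frac, reciprocal=True
            )

    tissue_unique: dict[str, PeakAtlas] = {}
    for tissue, atlas in consistent.items():
        others = union_atlas(
            [a for t, a in consistent.items() if t != tissue] or [PeakAtlas([])]
        )
        uniq = intersect(atlas, others, mode="unique_a")
        tissue_unique[tissue] = union_atlas([uniq])  # sort + merge

    layers: dict[str, list[PeakAtlas]] = {}
    for tissue, atlas in consistent.items():
        layers.setdefault(lineage_map[tissue], []).append(atlas)
    lineage = {layer: union_atlas(atlases) for layer, atlases in layers.items()}
    lineage_unique: dict[str, PeakAtlas] = {}
    for layer, atlas in lineage.items():
        others = union_atlas(
            [a for l, a in lineage.items() if l != layer] or [PeakAtlas([])]
        )
        uniq = intersect(atlas, others, mode="unique_a")
        lineage_unique[layer] = union_atlas([uniq])
    return TissueRegionSets(consistent, tissue_unique, lineage, lineage_unique, singles)


def class_region_enrichment(
    class_atlases: Mapping[str, PeakAtlas],
    region_sets: Mapping[str, PeakAtlas] | TissueRegionSets,
    universe: PeakAtlas,
) -> pd.DataFrame:
    """Enrichment of each enhancer class in each tissue/lineage region set.

    observed = class peaks with any (>=1 bp) overlap in the set; expected =
    |class| x (universe peaks overlapping the set / |universe|).  Empty
    region sets produce missing (censored) rows.
    """
    if isinstance(region_sets, TissueRegionSets):
        region_sets = region_sets.region_sets()
    n_universe = len(universe)
    rows = []
    for set_name, regions in region_sets.items():
        k_universe = len(intersect_any(universe, regions))
        for cls in sorted(class_atlases):
            atlas = class_atlases[cls]
            observed = len(intersect_any(atlas, regions))
            rows.append(
                enrichment_row(cls, set_name, observed, len(atlas), k_universe, n_universe)
            )
    return pd.DataFrame(rows)


def to_wide_scores(enrichment: pd.DataFrame, set_order: tuple[str, ...] = TISSUE_ORDER) -> pd.DataFrame:
    """Pivot the long enrichment table to class x set scores (radar-ready)."""
    wide = enrichment.pivot(index="class", columns="set", values="score")
    ordered = [s for s in set_order if s in wide.columns]
    rest = [s for s in wide.columns if s not in ordered]
    return wide[ordered + rest]
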