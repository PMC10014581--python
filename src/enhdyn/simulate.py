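"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions end to end: a five-stage
(ESC, ADE, VFGp3, VFGp6, PE) x two-replicate ATAC count matrix whose
dynamic peaks follow the six temporal archetypes; gene annotations and a
differential-expression table consistent with the planted enhancer-gene
links; duplicate-replicate foetal-tissue H3K27ac peak sets with class-
calibrated overlap; and two single-cell UMI datasets with partially
shared cluster signatures.  Every generator draws from its own named RNG
stream derived from one seed, so adding a generator never perturbs the
others and all outputs are byte-reproducible.

Planted enrichments are *fold-calibrated*: the observed/expected
statistic measures a class rate against the pooled dataset rate, which
includes the enriched class itself, so a naive hit rate of
``fold x background`` would realize less than ``fold``.  The generators
solve for the class rate that makes the realized observed/expected equal
the configured fold.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cat import CellMatrix
from .dynamics import DEFAULT_ARCHETYPES, AccessibilityMatrix, GROUP_NAMES
from .intervals import GenomicInterval, PeakAtlas

__all__ = [
    "SimulationConfig",
    "AtacSimulation",
    "simulate_atac_timecourse",
    "simulate_de_table",
    "simulate_enriched_gene_set",
    "simulate_tissue_h3k27ac",
    "simulate_scrna",
    "calibrated_rates",
]

STAGES = ("ESC", "ADE", "VFGp3", "VFGp6", "PE")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the study's own defaults."""

    seed: int = 0
    # ATAC time course
    stages: tuple[str, ...] = STAGES
    replicates_per_stage: int = 2
    n_peaks_per_group: int = 500
    n_static_peaks: int = 2000
    nb_dispersion: float = 0.1
    base_mean_range: tuple[float, float] = (30.0, 300.0)
    fold_change: float = 8.0
    peak_width_range: tuple[int, int] = (200, 1000)
    genome: tuple[tuple[str, int], ...] = (("chr1", 10_000_000), ("chr2", 10_000_000))
    library_size_range: tuple[float, float] = (8e6, 1.2e7)
    # genes / DE
    enhancer_gene_link_rate: float = 0.35
    n_noise_genes: int = 300
    gene_distance_range: tuple[int, int] = (2_500, 12_000)
    de_effect: float = 2.0
    # tissue H3K27ac (values are enrichment folds over the background rate)
    tissue_folds: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = (
        ("pancreas", (("PE^ON", 3.0), ("PE^PRIMED", 2.0))),
        ("liver", (("PE^PRIMED", 2.0), ("VFG^TR", 2.0), ("PE^OFF", 2.0))),
        ("heart", (("ADE^OFF", 2.5),)),
        ("adrenal", (("VFG^OFF", 2.5),)),
        ("brain", (("ADE^OFF", 2.5), ("VFG^OFF", 2.5))),
        ("RPE", (("VFG^OFF", 2.5),)),
        ("lung", ()),
        ("stomach", ()),
    )
    tissue_background_rate: float = 0.1
    tissue_private_regions: int = 300
    tissue_region_width_range: tuple[int, int] = (400, 900)
    tissue_jitter: float = 0.2
    single_replicate_tissues: tuple[str, ...] = ("stomach",)
    # scRNA
    scrna_clusters: int = 5
    scrna_cells_per_cluster: int = 100
    scrna_genes: int = 1500
    scrna_mito_genes: int = 10
    scrna_signature_size: int = 30
    scrna_signature_fold: float = 8.0
    scrna_dispersion: float = 0.3
    scrna_shared_clusters: int = 3
    scrna_mito_high_rate: float = 0.05
    scrna_low_depth_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.n_peaks_per_group < 0 or self.n_static_peaks < 0:
            raise ValueError("peak counts must be >= 0")
        if not 0 <= self.enhancer_gene_link_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.tissue_background_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")


def _stream(cfg_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# ATAC time course
# ---------------------------------------------------------------------------


@dataclass
class AtacSimulation:
    """A synthetic ATAC study with its planted ground truth."""

    matrix: AccessibilityMatrix
    atlas: PeakAtlas
    truth_groups: pd.Series  # peak -> archetype group or "static"
    gene_annotation: pd.DataFrame  # gene_id-indexed: chrom, start, end, strand, tss
    truth_links: pd.DataFrame  # columns peak, gene_id (the planted one-to-one links)
    gene_class: pd.Series  # gene -> class of its planted peak, or "noise"
    config: SimulationConfig = field(default_factory=SimulationConfig)


def _place_nonoverlapping(
    rng: np.random.Generator, widths: np.ndarray, genome: Sequence[tuple[str, int]]
) -> list[tuple[str, int, int]]:
    """Place intervals uniformly at random without overlap (stick-breaking)."""
    n = len(widths)
    chrom_names = [c for c, _ in genome]
    chrom_lens = np.array([l for _, l in genome], dtype=float)
    probs = chrom_lens / chrom_lens.sum()
    assignment = rng.choice(len(chrom_names), size=n, p=probs)
    placed: list[tuple[str, int, int]] = []
    for ci, (chrom, length) in enumerate(genome):
        idx = np.where(assignment == ci)[0]
        w = widths[idx]
        free = length - int(w.sum())
        if free < 0:
            raise ValueError(
                f"genome too small to place {len(idx)} peaks on {chrom}"
            )
        gaps = np.sort(rng.random(len(idx))) * free
        order = rng.permutation(len(idx))
        starts = (gaps + np.concatenate([[0], np.cumsum(w[order])[:-1]])).astype(int)
        for s, wi in zip(starts, w[order]):
            placed.append((chrom, int(s), int(s + wi)))
    placed.sort()
    return placed


def simulate_atac_timecourse(cfg: SimulationConfig | None = None) -> AtacSimulation:
    """Generate the peak atlas, count matrix, sample sheet, gene annotation
    and planted truth of the synthetic time course."""
    cfg = cfg or SimulationConfig()
    rng_peaks = _stream(cfg.seed, "peaks")
    rng_counts = _stream(cfg.seed, "counts")
    rng_genes = _stream(cfg.seed, "genes")

    groups = [g for g in GROUP_NAMES for _ in range(cfg.n_peaks_per_group)]
    groups += ["static"] * cfg.n_static_peaks
    n = len(groups)
    widths = rng_peaks.integers(
        cfg.peak_width_range[0], cfg.peak_width_range[1] + 1, size=n
    )
    placed = _place_nonoverlapping(rng_peaks, widths, cfg.genome)
    atlas = PeakAtlas(
        [GenomicInterval(c, s, e) for c, s, e in placed], "synthetic", presorted=True
    ).with_names()
    # peak order was sorted by coordinate; shuffle group labels onto peaks
    labels = np.array(groups, dtype=object)
    rng_peaks.shuffle(labels)
    peak_names = [iv.name for iv in atlas]
    truth_groups = pd.Series(labels, index=peak_names, name="group")

    # stage means: mu = base * fold^shape, shape in [0,1] from the archetype
    shape = np.zeros((n, len(cfg.stages)))
    for g, prof in DEFAULT_ARCHETYPES.items():
        shape[truth_groups.to_numpy() == g] = np.asarray(prof)
    lo, hi = cfg.base_mean_range
    base = np.exp(rng_counts.uniform(np.log(lo), np.log(hi), size=n))
    length_factor = np.array([iv.length for iv in atlas]) / 500.0
    stage_mu = base[:, None] * cfg.fold_change ** shape * 1.0

    samples, lib_sizes, stage_of = [], [], []
    for stage in cfg.stages:
        for r in range(1, cfg.replicates_per_stage + 1):
            samples.append(f"{stage}_rep{r}")
            stage_of.append(stage)
            lib_sizes.append(rng_counts.uniform(*cfg.library_size_range))
    lib = np.asarray(lib_sizes)
    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, stage in enumerate(stage_of):
        si = cfg.stages.index(stage)
        mean = stage_mu[:, si] * length_factor * (lib[j] / 1e7)
        if cfg.nb_dispersion > 0:
            lam = rng_counts.gamma(
                1.0 / cfg.nb_dispersion, scale=mean * cfg.nb_dispersion
            )
        else:
            lam = mean
        counts[:, j] = rng_counts.poisson(lam)
    sample_sheet = pd.DataFrame(
        {
            "stage": stage_of,
            "replicate": [int(s.rsplit("rep", 1)[1]) for s in samples],
            "library_size": lib,
        },
        index=pd.Index(samples, name="sample"),
    )
    matrix = AccessibilityMatrix(
        counts=pd.DataFrame(counts, index=peak_names, columns=samples),
        atlas=atlas,
        samples=sample_sheet,
        stage_order=cfg.stages,
    )

    gene_annotation, truth_links, gene_class = _plant_genes(cfg, atlas, truth_groups, rng_genes)
    return AtacSimulation(
        matrix, atlas, truth_groups, gene_annotation, truth_links, gene_class, cfg
    )


def _plant_genes(
    cfg: SimulationConfig,
    atlas: PeakAtlas,
    truth_groups: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Plant one target gene near a fraction of classified peaks, plus
    unlinked noise genes scattered over the genome."""
    chrom_len = dict(cfg.genome)
    records, link_rows = [], []
    gi = 0
    for iv in atlas:
        if truth_groups[iv.name] == "static":
            continue
        if rng.random() >= cfg.enhancer_gene_link_rate:
            continue
        gi += 1
        gene = f"G{gi:05d}"
        d = int(rng.integers(*cfg.gene_distance_range))
        side = 1 if rng.random() < 0.5 else -1
        tss = int(np.clip(iv.midpoint + side * d, 0, chrom_len[iv.chrom] - 2))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = (tss, tss + 1000) if strand == "+" else (max(tss - 999, 0), tss + 1)
        records.append((gene, iv.chrom, start, end, strand, tss))
        link_rows.append((iv.name, gene))
    for _ in range(cfg.n_noise_genes):
        gi += 1
        gene = f"G{gi:05d}"
        chrom = cfg.genome[int(rng.integers(len(cfg.genome)))][0]
        tss = int(rng.integers(0, chrom_len[chrom] - 1001))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = (tss, tss + 1000) if strand == "+" else (max(tss - 999, 0), tss + 1)
        records.append((gene, chrom, start, end, strand, tss))
    ann = pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    ).set_index("gene_id")
    links = pd.DataFrame(link_rows, columns=["peak", "gene_id"])
    gene_class = pd.Series("noise", index=ann.index, dtype=object)
    linked_peaks = links.set_index("gene_id")["peak"]
    gene_class.loc[linked_peaks.index] = truth_groups[linked_peaks.values].to_numpy()
    return ann, links, gene_class


# ---------------------------------------------------------------------------
# DE table and planted gene sets
# ---------------------------------------------------------------------------

UP_CLASSES = ("PE^PRIMED", "PE^ON")
DOWN_CLASSES = ("PE^OFF", "VFG^TR")


def simulate_de_table(
    sim: AtacSimulation, effect: float | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Differential-expression table consistent with the planted links.

    Genes planted next to priming/opening classes are upregulated with
    log2FC around ``effect``; genes next to decommissioned classes are
    downregulated; everything else (including noise genes) is null.
    """
    cfg = sim.config
    effect = cfg.de_effect if effect is None else effect
    rng = _stream(cfg.seed if seed is None else seed, "de_table")
    genes = sim.gene_class.index
    n = len(genes)
    base = np.exp(rng.uniform(np.log(10.0), np.log(3e4), size=n))
    lfc = rng.normal(0.0, 0.3, size=n)
    padj = rng.uniform(0.0, 1.0, size=n)
    cls = sim.gene_class.to_numpy()
    up = np.isin(cls, UP_CLASSES)
    down = np.isin(cls, DOWN_CLASSES)
    sig = up | down
    base[sig] = np.exp(rng.uniform(np.log(2e3), np.log(3e4), size=int(sig.sum())))
    lfc[up] = effect + rng.normal(0.0, 0.15, size=int(up.sum()))
    lfc[down] = -effect + rng.normal(0.0, 0.15, size=int(down.sum()))
    padj[sig] = np.exp(rng.uniform(np.log(1e-8), np.log(1e-3), size=int(sig.sum())))
    return pd.DataFrame(
        {"baseMean": base, "log2FoldChange": lfc, "padj": padj},
        index=pd.Index(genes, name="gene"),
    )


def calibrated_rates(
    n_by_class: Mapping[str, int],
    folds: Mapping[str, float],
    background_rate: float,
) -> dict[str, float]:
    """Per-class hit rates whose realized observed/expected equals the fold.

    Solves p = background * N_bg / (N - sum_enriched n_c * f_c) for the
    pooled rate p, then sets rate_c = f_c * p for enriched classes and
    ``background_rate`` for the rest.
    """
    n_total = sum(n_by_class.values())
    n_enr = {c: n_by_class.get(c, 0) for c in folds}
    denom = n_total - sum(n * folds[c] for c, n in n_enr.items())
    if denom <= 0:
        raise ValueError("enrichment folds too large for the class sizes")
    pooled = background_rate * (n_total - sum(n_enr.values())) / denom
    rates = {c: background_rate for c in n_by_class}
    for c, f in folds.items():
        if c in rates:
            rates[c] = f * pooled
    capped = {c: r for c, r in rates.items() if r > 0.95}
    if capped:
        warnings.warn(f"calibrated rates capped at 0.95: {capped}")
        rates = {c: min(r, 0.95) for c, r in rates.items()}
    return rates


def simulate_enriched_gene_set(
    links: pd.DataFrame,
    class_labels: pd.Series,
    folds: Mapping[str, float],
    background_rate: float = 0.1,
    seed: int = 0,
) -> set[str]:
    """Draw a gene set with a planted fold over-representation of the
    target classes' linked genes (fold-calibrated; see module docstring)."""
    tab = links[["peak", "gene_id"]].drop_duplicates(subset="peak").copy()
    tab["class"] = tab["peak"].map(class_labels)
    tab = tab.dropna(subset=["class"])
    n_by_class = tab.groupby("class").size().to_dict()
    rates = calibrated_rates(n_by_class, folds, background_rate)
    rng = _stream(seed, "gene_set")
    # decide per gene from the class of its first linking peak
    first = tab.sort_values("peak").drop_duplicates(subset="gene_id")
    hit = rng.random(len(first)) < first["class"].map(rates).to_numpy(dtype=float)
    return set(first.loc[hit, "gene_id"])


# ---------------------------------------------------------------------------
# Tissue H3K27ac replicate sets
# ---------------------------------------------------------------------------


def simulate_tissue_h3k27ac(
    sim: AtacSimulation,
    folds: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | None = None,
) -> tuple[dict[str, tuple[PeakAtlas, ...]], pd.DataFrame]:
    """Per-tissue replicate H3K27ac peak sets with class-calibrated overlap.

    For each tissue, every atlas peak is overlapped by a tissue region with
    the fold-calibrated probability of its class; tissue-private background
    regions are placed in peak-free gaps.  Replicates jitter region edges
    by at most ``tissue_jitter`` x length, so the 50% reciprocal filter
    retains nearly all regions.  Returns (tissue -> replicate atlases,
    truth table of planted regions).
    """
    cfg = sim.config
    rng = _stream(cfg.seed if seed is None else seed, "tissues")
    if folds is None:
        folds = {t: dict(f) for t, f in cfg.tissue_folds}
    chrom_len = dict(cfg.genome)
    n_by_class = sim.truth_groups.groupby(sim.truth_groups).size().to_dict()
    out: dict[str, tuple[PeakAtlas, ...]] = {}
    truth_rows = []
    for tissue in folds:
        rates = calibrated_rates(n_by_class, folds[tissue], cfg.tissue_background_rate)
        regions: list[tuple[str, int, int, str]] = []
        for iv in sim.atlas:
            if rng.random() < rates[sim.truth_groups[iv.name]]:
                w = int(rng.integers(*cfg.tissue_region_width_range))
                s = max(0, iv.midpoint - w // 2)
                regions.append((iv.chrom, s, min(s + w, chrom_len[iv.chrom]), iv.name))
        regions.extend(
            _private_regions(cfg, sim.atlas, rng, cfg.tissue_private_regions)
        )
        n_reps = 1 if tissue in cfg.single_replicate_tissues else 2
        reps = []
        for rep in range(n_reps):
            ivs = []
            for ri, (chrom, s, e, _src) in enumerate(regions):
                length = e - s
                js = int(rng.integers(-int(cfg.tissue_jitter * length),
                                      int(cfg.tissue_jitter * length) + 1))
                je = int(rng.integers(-int(cfg.tissue_jitter * length),
                                      int(cfg.tissue_jitter * length) + 1))
                ns, ne = max(0, s + js), min(e + je, chrom_len[chrom])
                if ne <= ns:
                    ns, ne = s, e
                ivs.append(
                    GenomicInterval(chrom, ns, ne, f"{tissue}_r{rep + 1}_{ri + 1:05d}")
                )
            reps.append(PeakAtlas(ivs, "synthetic"))
        out[tissue] = tuple(reps)
        for chrom, s, e, src in regions:
            truth_rows.append((tissue, chrom, s, e, src))
    truth = pd.DataFrame(
        truth_rows, columns=["tissue", "chrom", "start", "end", "source_peak"]
    )
    return out, truth


def _private_regions(
    cfg: SimulationConfig,
    atlas: PeakAtlas,
    rng: np.random.Generator,
    n_regions: int,
    max_tries: int = 50,
) -> list[tuple[str, int, int, str]]:
    """Background regions placed so as not to overlap any atlas peak."""
    chrom_len = dict(cfg.genome)
    regions = []
    for _ in range(n_regions):
        for _try in range(max_tries):
            chrom = cfg.genome[int(rng.integers(len(cfg.genome)))][0]
            w = int(rng.integers(*cfg.tissue_region_width_range))
            s = int(rng.integers(0, chrom_len[chrom] - w))
            probe = PeakAtlas([GenomicInterval(chrom, s, s + w)])
            from .intervals import intersect_any

            if len(intersect_any(probe, atlas)) == 0:
                regions.append((chrom, s, s + w, "background"))
                break
    return regions


# ---------------------------------------------------------------------------
# Single-cell datasets
# ---------------------------------------------------------------------------


@dataclass
class ScrnaSimulation:
    dataset_a: CellMatrix
    dataset_b: CellMatrix
    labels_a: pd.Series
    labels_b: pd.Series
    shared_pairs: dict[str, str]  # A-cluster -> B-cluster with the same signature


def simulate_scrna(cfg: SimulationConfig | None = None) -> ScrnaSimulation:
    """Two clustered UMI datasets whose first ``scrna_shared_clusters``
    clusters share signature gene programs across datasets."""
    cfg = cfg or SimulationConfig()
    rng = _stream(cfg.seed, "scrna")
    n_mito = cfg.scrna_mito_genes
    gene_names = [f"MT-{i + 1}" for i in range(n_mito)] + [
        f"GENE{i + 1:05d}" for i in range(cfg.scrna_genes - n_mito)
    ]
    non_mito = gene_names[n_mito:]
    base = np.exp(rng.normal(np.log(4.0), 0.6, size=len(gene_names)))
    base[:n_mito] = np.exp(rng.normal(np.log(15.0), 0.3, size=n_mito))  # ~2% mito

    k = cfg.scrna_clusters
    shared = cfg.scrna_shared_clusters
    n_programs = shared + 2 * (k - shared)
    pool = rng.permutation(len(non_mito))[: n_programs * cfg.scrna_signature_size]
    programs = [
        [non_mito[g] for g in pool[i * cfg.scrna_signature_size : (i + 1) * cfg.scrna_signature_size]]
        for i in range(n_programs)
    ]
    sig_a = {f"A{i + 1}": programs[i if i < shared else shared + (i - shared)] for i in range(k)}
    sig_b = {
        f"B{i + 1}": programs[i if i < shared else shared + (k - shared) + (i - shared)]
        for i in range(k)
    }
    shared_pairs = {f"A{i + 1}": f"B{i + 1}" for i in range(shared)}

    def build(signatures: dict[str, list[str]], tag: str) -> tuple[CellMatrix, pd.Series]:
        rows, labels, names = [], [], []
        gene_idx = {g: i for i, g in enumerate(gene_names)}
        for cluster, sig in signatures.items():
            mean = base.copy()
            sel = [gene_idx[g] for g in sig]
            mean[sel] = mean[sel] * cfg.scrna_signature_fold
            for c in range(cfg.scrna_cells_per_cluster):
                depth = 1.0
                m = mean.copy()
                if rng.random() < cfg.scrna_low_depth_rate:
                    depth = 0.15
                if rng.random() < cfg.scrna_mito_high_rate:
                    m[:n_mito] = m[:n_mito] * 25.0
                lam = rng.gamma(
                    1.0 / cfg.scrna_dispersion,
                    scale=m * depth * cfg.scrna_dispersion,
                )
                rows.append(rng.poisson(lam))
                labels.append(cluster)
                names.append(f"{tag}_{cluster}_c{c + 1:03d}")
        counts = pd.DataFrame(
            np.asarray(rows), index=names, columns=gene_names
        )
        meta = pd.DataFrame({"cluster": labels}, index=names)
        return CellMatrix(counts, meta), pd.Series(labels, index=names, name="cluster")

    mat_a, lab_a = build(sig_a, "A")
    mat_b, lab_b = build(sig_b, "B")
    return ScrnaSimulation(mat_a, mat_b, lab_a, lab_b, shared_pairs)
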