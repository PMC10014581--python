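"""End-to-end orchestration: simulate or load a workspace, then run
intervals -> dynamics -> classes -> linking -> enrichment -> CAT.

A workspace is a directory with ``inputs/`` (BED/TSV files in the formats
the readers consume) and ``results/`` (tables, class BED files and a run
manifest).  Every stage is a function over the workspace so the CLI verbs
can run them independently; ``run_pipeline`` chains them and writes a
manifest with the seed, thresholds and input checksums.  Reruns with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cat import (
    CellMatrix,
    align_clusters,
    bootstrap_cluster_profiles,
    highly_variable_panel,
    lognormalize,
    qc_filter_cells,
    scale_cells,
)
from .dynamics import (
    AccessibilityMatrix,
    DEFAULT_ARCHETYPES,
    assign_groups,
    cmeans_cluster,
    detect_dynamic_peaks,
    pairwise_open_close,
    read_counts_tsv,
    read_sample_sheet,
    rpkm_normalize,
    standardize_trajectories,
)
from .enrichment import (
    TISSUE_ORDER,
    build_tissue_sets,
    class_geneset_enrichment,
    class_region_enrichment,
    to_wide_scores,
)
from .genes import (
    filter_de_genes,
    filter_promoter_distal,
    nearest_tss_assignment,
    read_de_table,
    read_gene_annotation,
)
from .intervals import (
    GenomicInterval,
    PeakAtlas,
    consensus_atlas,
    read_bed,
    reproducible_peaks,
    union_atlas,
    write_bed,
)
from .simulate import (
    STAGES,
    SimulationConfig,
    simulate_atac_timecourse,
    simulate_de_table,
    simulate_scrna,
    simulate_tissue_h3k27ac,
)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_workspace"]

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Every threshold of the analysis, surfaced as a named key."""

    seed: int = 0
    stage_order: tuple[str, ...] = STAGES
    # dynamics
    dynamics_lfc_threshold: float = 2.0
    dynamics_padj_threshold: float = 0.005
    n_clusters: int = 8
    fuzzifier_m: float = 1.25
    promoter_tss_window: int = 2_000
    pairwise_lfc_threshold: float = 1.0
    pairwise_padj_threshold: float = 0.05
    # DE gene sets
    de_base_mean_min: float = 1_000.0
    de_lfc_min: float = 1.5
    de_padj_max: float = 0.05
    # linking
    link_windows: tuple[int, ...] = (25_000, 200_000)
    # tissue filter
    tissue_min_frac: float = 0.5
    # CAT
    n_boot: int = 1_000
    cat_alpha: float = 0.01
    qc_umi_bounds: tuple[float, float] = (2_000, 35_000)
    qc_gene_bounds: tuple[float, float] = (550, 4_950)
    qc_mito_max: float = 0.20
    run_cat: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if len(self.stage_order) < 2:
            raise ValueError("stage order must list >=2 stages")
        # one pipeline-level seed fans out everywhere
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()},
                  simulation=sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


# ---------------------------------------------------------------------------
# Workspace materialisation
# ---------------------------------------------------------------------------


def simulate_workspace(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Generate every input the pipeline consumes into ``outdir/inputs``."""
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    sim = simulate_atac_timecourse(cfg.simulation)

    write_bed(sim.atlas, inputs / "atlas.bed")
    _write_tsv(sim.matrix.counts, inputs / "counts.tsv")
    _write_tsv(sim.matrix.samples, inputs / "samples.tsv")
    ann = sim.gene_annotation[["chrom", "start", "end", "strand"]].copy()
    ann.insert(0, "gene_id", ann.index)
    ann = ann[["gene_id", "chrom", "start", "end", "strand"]]
    ann.to_csv(inputs / "genes.tsv", sep="\t", header=False, index=False)
    de = simulate_de_table(sim)
    _write_tsv(de.reset_index(), inputs / "de_table.tsv", index=False)
    _write_tsv(sim.truth_groups.to_frame(), inputs / "truth_groups.tsv")
    _write_tsv(sim.truth_links, inputs / "truth_links.tsv", index=False)

    # per-stage replicate peak calls (accessible peaks, edges jittered <=10%)
    rng = np.random.default_rng([cfg.seed, 777])
    shapes = {g: np.asarray(p) for g, p in DEFAULT_ARCHETYPES.items()}
    stage_dir = inputs / "stage_peaks"
    stage_dir.mkdir(exist_ok=True)
    for si, stage in enumerate(cfg.simulation.stages):
        accessible = [
            iv
            for iv in sim.atlas
            if sim.truth_groups[iv.name] == "static"
            or shapes[sim.truth_groups[iv.name]][si] >= 0.5
        ]
        for rep in (1, 2):
            ivs = []
            for iv in accessible:
                j = int(0.1 * iv.length)
                s = max(0, iv.start + int(rng.integers(-j, j + 1)))
                e = max(s + 1, iv.end + int(rng.integers(-j, j + 1)))
                ivs.append(GenomicInterval(iv.chrom, s, e))
            write_bed(PeakAtlas(ivs), stage_dir / f"{stage}_rep{rep}.bed")

    tissues, tissue_truth = simulate_tissue_h3k27ac(sim)
    tissue_dir = inputs / "tissues"
    tissue_dir.mkdir(exist_ok=True)
    for tissue, reps in tissues.items():
        for i, atlas in enumerate(reps, start=1):
            write_bed(atlas, tissue_dir / f"{tissue}_rep{i}.bed")
    _write_tsv(tissue_truth, inputs / "truth_tissue_regions.tsv", index=False)

    sc = simulate_scrna(cfg.simulation)
    _write_tsv(sc.dataset_a.counts, inputs / "scrna_a_counts.tsv")
    _write_tsv(sc.dataset_b.counts, inputs / "scrna_b_counts.tsv")
    _write_tsv(sc.labels_a.to_frame(), inputs / "scrna_a_clusters.tsv")
    _write_tsv(sc.labels_b.to_frame(), inputs / "scrna_b_clusters.tsv")
    with open(inputs / "truth_scrna_shared.json", "w") as fh:
        json.dump(sc.shared_pairs, fh, sort_keys=True, indent=1)
    return outdir


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _load_matrix(inputs: Path, cfg: PipelineConfig) -> AccessibilityMatrix:
    sheet = inputs / "samples.tsv"
    if not sheet.exists():
        raise FileNotFoundError(f"missing sample sheet: {sheet}")
    counts = read_counts_tsv(inputs / "counts.tsv")
    samples = read_sample_sheet(sheet)
    atlas = read_bed(inputs / "atlas.bed")
    return AccessibilityMatrix(counts, atlas, samples, cfg.stage_order)


def stage_intervals(workspace: Path, cfg: PipelineConfig) -> dict:
    """Rebuild the consensus atlas from per-stage replicate peak calls."""
    inputs = workspace / "inputs"
    results = workspace / "results"
    results.mkdir(exist_ok=True)
    per_stage = []
    for stage in cfg.stage_order:
        rep_paths = sorted((inputs / "stage_peaks").glob(f"{stage}_rep*.bed"))
        if not rep_paths:
            raise FileNotFoundError(f"no replicate peak files for stage {stage}")
        reps = [read_bed(p) for p in rep_paths]
        per_stage.append(
            reps[0] if len(reps) == 1 else reproducible_peaks(reps[0], reps[1])
        )
    consensus = consensus_atlas(per_stage)
    write_bed(consensus, results / "consensus_rebuilt.bed")
    planted = read_bed(inputs / "atlas.bed")
    union = union_atlas([consensus, planted])
    inter = consensus.covered_bases() + planted.covered_bases() - union.covered_bases()
    return {
        "n_consensus_rebuilt": len(consensus),
        "consensus_vs_atlas_jaccard": round(inter / union.covered_bases(), 4),
    }


def stage_dynamics(workspace: Path, cfg: PipelineConfig) -> dict:
    inputs = workspace / "inputs"
    results = workspace / "results"
    results.mkdir(exist_ok=True)
    m = _load_matrix(inputs, cfg)
    genes = read_gene_annotation(inputs / "genes.tsv")
    distal = filter_promoter_distal(m.atlas, genes, cfg.promoter_tss_window)
    distal_names = [iv.name for iv in distal]
    m_distal = AccessibilityMatrix(
        m.counts.loc[distal_names], m.atlas, m.samples, cfg.stage_order
    )
    dyn = detect_dynamic_peaks(
        m_distal, cfg.dynamics_lfc_threshold, cfg.dynamics_padj_threshold
    )
    _write_tsv(dyn, results / "dynamic_peaks.tsv")
    norm = rpkm_normalize(m_distal)
    traj = standardize_trajectories(norm, m.samples, cfg.stage_order, dyn["is_dynamic"])
    fcm = cmeans_cluster(
        traj, k=cfg.n_clusters, fuzzifier_m=cfg.fuzzifier_m, seed=cfg.seed
    )
    fcm = assign_groups(fcm)
    classification = pd.DataFrame(
        {
            "cluster": fcm.hard_cluster,
            "membership_score": fcm.membership_score,
            "group": fcm.group,
        }
    )
    classification.index.name = "peak"
    _write_tsv(classification, results / "classification.tsv")
    for group in sorted(classification["group"].unique()):
        names = classification.index[classification["group"] == group]
        atlas = PeakAtlas([m.atlas.id_index[p] for p in names])
        write_bed(atlas, results / f"class_{group.replace('^', '_')}.bed")
    return {
        "n_peaks": len(m.counts),
        "n_promoter_distal": len(distal_names),
        "n_dynamic": int(dyn["is_dynamic"].sum()),
        "n_groups": int(classification["group"].nunique()),
        "cluster_to_group": {str(k): v for k, v in sorted(fcm.cluster_to_group.items())},
    }


def stage_classes(workspace: Path, cfg: PipelineConfig) -> dict:
    inputs = workspace / "inputs"
    results = workspace / "results"
    results.mkdir(parents=True, exist_ok=True)
    m = _load_matrix(inputs, cfg)
    pairwise = pairwise_open_close(
        m, cfg.pairwise_lfc_threshold, cfg.pairwise_padj_threshold
    )
    out = pairwise.to_frame("class")
    out.index.name = "peak"
    _write_tsv(out, results / "pairwise_classes.tsv")
    for cls in sorted(c for c in pairwise.unique() if c != "none"):
        names = pairwise.index[pairwise == cls]
        write_bed(
            PeakAtlas([m.atlas.id_index[p] for p in names]),
            results / f"class_{cls.replace('^', '_')}.bed",
        )
    counts = pairwise.value_counts().to_dict()
    return {"pairwise_counts": {str(k): int(v) for k, v in sorted(counts.items())}}


def stage_link(workspace: Path, cfg: PipelineConfig) -> dict:
    inputs = workspace / "inputs"
    results = workspace / "results"
    results.mkdir(parents=True, exist_ok=True)
    atlas = read_bed(inputs / "atlas.bed")
    genes = read_gene_annotation(inputs / "genes.tsv")
    info = {}
    for window in cfg.link_windows:
        links = nearest_tss_assignment(atlas, genes, window)
        _write_tsv(links, results / f"links_{window // 1000}kb.tsv", index=False)
        info[f"n_links_{window // 1000}kb"] = len(links)
    return info


def stage_enrich(workspace: Path, cfg: PipelineConfig) -> dict:
    inputs = workspace / "inputs"
    results = workspace / "results"
    results.mkdir(parents=True, exist_ok=True)
    de = read_de_table(inputs / "de_table.tsv")
    classification = pd.read_csv(results / "classification.tsv", sep="\t", index_col=0)
    class_labels = classification["group"]
    sets = {
        "PE_up": filter_de_genes(
            de, cfg.de_base_mean_min, cfg.de_lfc_min, cfg.de_padj_max, "up"
        ),
        "PE_down": filter_de_genes(
            de, cfg.de_base_mean_min, cfg.de_lfc_min, cfg.de_padj_max, "down"
        ),
    }
    frames = []
    for window in cfg.link_windows:
        links = pd.read_csv(results / f"links_{window // 1000}kb.tsv", sep="\t")
        for set_name, gene_set in sets.items():
            enr = class_geneset_enrichment(
                links, class_labels, gene_set, f"{set_name}_{window // 1000}kb"
            )
            frames.append(enr)
    geneset_enr = pd.concat(frames, ignore_index=True)
    _write_tsv(geneset_enr, results / "geneset_enrichment.tsv", index=False)

    tissue_reps: dict[str, tuple[PeakAtlas, ...]] = {}
    for bed in sorted((inputs / "tissues").glob("*_rep*.bed")):
        tissue = bed.stem.rsplit("_rep", 1)[0]
        tissue_reps.setdefault(tissue, ())
        tissue_reps[tissue] = tissue_reps[tissue] + (read_bed(bed),)
    region_sets = build_tissue_sets(tissue_reps, min_frac=cfg.tissue_min_frac)
    universe = read_bed(inputs / "atlas.bed")
    class_atlases = {
        g: PeakAtlas(
            [universe.id_index[p] for p in class_labels.index[class_labels == g]]
        )
        for g in sorted(class_labels.dropna().unique())
    }
    region_enr = class_region_enrichment(class_atlases, region_sets, universe)
    _write_tsv(region_enr, results / "tissue_enrichment.tsv", index=False)
    tissue_only = region_enr[region_enr["set"].isin(TISSUE_ORDER)]
    _write_tsv(to_wide_scores(tissue_only), results / "tissue_enrichment_wide.tsv")
    return {
        "n_up_genes": len(sets["PE_up"]),
        "n_down_genes": len(sets["PE_down"]),
        "n_tissue_sets": len(region_sets.region_sets()),
    }


def stage_cat(workspace: Path, cfg: PipelineConfig) -> dict:
    inputs = workspace / "inputs"
    results = workspace / "results"
    results.mkdir(parents=True, exist_ok=True)
    mats = {}
    for tag in ("a", "b"):
        counts = pd.read_csv(inputs / f"scrna_{tag}_counts.tsv", sep="\t", index_col=0)
        labels = pd.read_csv(
            inputs / f"scrna_{tag}_clusters.tsv", sep="\t", index_col=0
        )["cluster"]
        cm = CellMatrix(counts, labels.to_frame("cluster"))
        cm, qc_log = qc_filter_cells(
            cm, cfg.qc_umi_bounds, cfg.qc_gene_bounds, cfg.qc_mito_max
        )
        mats[tag] = (cm, qc_log)
    norm_a = scale_cells(lognormalize(mats["a"][0]))
    norm_b = scale_cells(lognormalize(mats["b"][0]))
    panel = highly_variable_panel(norm_a, norm_b)
    prof_a = bootstrap_cluster_profiles(
        norm_a, mats["a"][0].meta["cluster"], panel, cfg.n_boot, seed=cfg.seed
    )
    prof_b = bootstrap_cluster_profiles(
        norm_b, mats["b"][0].meta["cluster"], panel, cfg.n_boot, seed=cfg.seed + 1
    )
    alignment = align_clusters(prof_a, prof_b, alpha=cfg.cat_alpha)
    _write_tsv(alignment, results / "cat_alignment.tsv", index=False)
    sig = alignment[alignment["significant"]]
    return {
        "qc_a": mats["a"][1],
        "qc_b": mats["b"][1],
        "panel_size": len(panel),
        "significant_alignments": [
            [r.source, r.target] for r in sig.itertuples()
        ],
    }


def run_pipeline(cfg: PipelineConfig, outdir: str | Path, simulate: bool = True) -> Path:
    """Run every stage in dependency order and write the run manifest."""
    workspace = Path(outdir)
    if simulate:
        simulate_workspace(cfg, workspace)
    inputs = workspace / "inputs"
    if not (inputs / "samples.tsv").exists():
        raise FileNotFoundError(f"missing sample sheet: {inputs / 'samples.tsv'}")
    (workspace / "results").mkdir(exist_ok=True)
    manifest: dict = {
        "tool": "enhdyn",
        "version": __version__,
        "seed": cfg.seed,
        "config": _jsonable(cfg.to_dict()),
        "note": "replicate reproducibility via reciprocal-overlap filter "
        "(IDR substitution)",
        "stages": {},
    }
    for name, fn in (
        ("intervals", stage_intervals),
        ("dynamics", stage_dynamics),
        ("classes", stage_classes),
        ("link", stage_link),
        ("enrich", stage_enrich),
        ("cat", stage_cat),
    ):
        if name == "cat" and not cfg.run_cat:
            continue
        try:
            manifest["stages"][name] = fn(workspace, cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest["input_checksums"] = {
        str(p.relative_to(workspace)): _sha256(p)
        for p in sorted(inputs.rglob("*"))
        if p.is_file()
    }
    with open(workspace / "results" / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return workspace


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
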