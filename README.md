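# enhdyn

Enhancer-accessibility dynamics for differentiation time courses:
temporal classification of ATAC-seq peaks, enhancer–gene linking,
observed/expected region-set enrichment, and bootstrap cluster alignment
of single-cell RNA-seq datasets — with a synthetic-data module that
generates every input with planted ground truth.

## Who this is for

Computational biologists analysing a staged differentiation experiment —
here, human embryonic stem cells (ESC) differentiating through anterior
definitive endoderm (ADE) and expanding ventral-foregut progenitors
(VFG, passages 3 and 6) to pancreatic endoderm (PE) — who want to ask:
which putative enhancers open or close at which stage, which genes do
they plausibly regulate, do enhancer classes concentrate near
up/down-regulated genes or inside foetal-tissue H3K27ac enhancer sets,
and how do in vitro scRNA-seq clusters map onto in vivo ones?

## The models at the core

**Dynamic accessibility.** Peak counts y over samples follow a
negative-binomial GLM with log link, a single stage factor and a log
library-size offset: log E[yᵢ] = βₛ₍ᵢ₎ + log eᵢ, Var[y] = μ + αμ².
Dispersions α are method-of-moments estimates shrunk toward a Cox–Reid
adjusted global profile-likelihood estimate. The stage factor is tested
by likelihood ratio (χ², S−1 df), BH-adjusted across peaks; a peak is
*dynamic* when |log₂FC| > 2 and padj < 0.005 (both strict).

**Temporal classes.** Dynamic trajectories (z-scored stage means of
log₂(RPKM+1)) are soft-clustered by fuzzy c-means (k = 8, fuzzifier
m = 1.25), and centroids are merged by correlation with six named
archetypes: ADE^OFF, VFG^OFF, PE^OFF, PE^ON, VFG^TR and PE^PRIMED.
Pairwise expansion classes (VFGp3^OPEN/CLOSE, VFGp6^OPEN/CLOSE) and
cross-protocol classes (PE-PP1-common, PE-not-PP1, VFG^OFF-in-DE-PP1,
VFG^TR-in-PP1) are derived from stage-pair tests and interval algebra.

**Enrichment.** For class c against a gene set or region set,
score = log₂(observed/expected) with expected = n_c × column/grand
total (the 2-way contingency expectation), tested by 1-df χ² on the
2×2 table without continuity correction.

**Cluster alignment (CAT).** Per-cluster mean expression over a shared
highly-variable gene panel is bootstrap-resampled 1,000 times; clusters
align to the target with the smallest mean Euclidean distance, declared
significant when the nearest distance distribution separates from the
next rank by a scale-free margin (one-sided Welch test).

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
from enhdyn.simulate import SimulationConfig, simulate_atac_timecourse, simulate_de_table
from enhdyn.dynamics import (detect_dynamic_peaks, rpkm_normalize,
                             standardize_trajectories, cmeans_cluster, assign_groups)
from enhdyn.genes import nearest_tss_assignment, filter_de_genes
from enhdyn.enrichment import class_geneset_enrichment

sim = simulate_atac_timecourse(SimulationConfig(seed=42))
dyn = detect_dynamic_peaks(sim.matrix)
print(f"dynamic peaks: {int(dyn.is_dynamic.sum())} of {len(dyn)}")

traj = standardize_trajectories(rpkm_normalize(sim.matrix), sim.matrix.samples,
                                sim.matrix.stage_order, dyn.is_dynamic)
fcm = assign_groups(cmeans_cluster(traj, k=8, seed=42))
print(fcm.group.value_counts().sort_index().to_string())

links = nearest_tss_assignment(sim.atlas, sim.gene_annotation, window=200_000)
up = filter_de_genes(simulate_de_table(sim), direction="up")
enr = class_geneset_enrichment(links, fcm.group, up, "PE_up")
print(enr[["class", "observed", "expected", "score", "pvalue"]].round(3).to_string(index=False))
```

prints

```
dynamic peaks: 2975 of 5000
ADE^OFF      501
PE^OFF       501
PE^ON        491
PE^PRIMED    492
VFG^OFF      491
VFG^TR       499
    class  observed  expected  score  pvalue
  ADE^OFF       118   137.922 -0.225   0.029
   PE^OFF       116   137.922 -0.250   0.016
    PE^ON       171   135.169  0.339   0.000
PE^PRIMED       185   135.445  0.450   0.000
  VFG^OFF       112   135.169 -0.271   0.010
   VFG^TR       117   137.372 -0.232   0.025
```

The simulation plants 500 peaks per archetype (plus 2,000 static): the
stage test flags essentially all of them, c-means recovers the six
groups at close to their planted sizes, and only the priming/opening
classes (PE^PRIMED, PE^ON) are enriched near the upregulated gene set —
the planted association.

## Command line

```sh
enhdyn run-all --seed 11 --outdir workspace     # simulate + full analysis
enhdyn simulate --seed 11 --outdir workspace    # inputs only
enhdyn dynamics|classes|link|enrich|cat --outdir workspace   # single stages
enhdyn consensus --out consensus.bed rep1a.bed,rep1b.bed rep2a.bed,rep2b.bed
```

`run-all` writes `workspace/results/` with the dynamic-peak table,
classification and per-class BED files, pairwise classes, 25/200 kb link
tables, gene-set and tissue enrichment tables, the CAT alignment report,
and a `manifest.json` recording the seed, every threshold and input
checksums. Reruns with the same seed are byte-identical.

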