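# Methods

`enhdyn` implements a regulatory-genomics analysis for a five-stage
differentiation time course (ESC → ADE → VFGp3 → VFGp6 → PE, i.e. embryonic
stem cells through anterior definitive endoderm and expanding ventral-foregut
progenitors to pancreatic endoderm): it classifies putative enhancers by
their temporal chromatin-accessibility dynamics, links them to genes, scores
their enrichment against differential-expression gene sets and foetal-tissue
H3K27ac enhancer sets, and aligns single-cell RNA-seq clusters between
datasets by bootstrap resampling.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not demonstrate.

## Interval algebra

All coordinates are BED convention (0-based, half-open).  Chromosome names
are compared by exact string match: `chr1` ≠ `1`, so assembly mismatches
fail loudly rather than returning silently empty overlaps.

The fraction-overlap test (`intersect`, modes `report_a` / `unique_a`,
optional reciprocal requirement) mirrors `bedtools intersect -f F [-r] -u`
and `-v`.  The comparison `overlap ≥ F·length` is evaluated in exact
rational arithmetic (`fractions.Fraction` over integer base pairs), so
boundary cases such as a 50 bp overlap of a 100 bp interval at F = 0.5 are
decided without floating-point ties.  Replicate reproducibility uses the
reciprocal 50% filter (`-f 0.50 -r -u`).  A full irreproducible-discovery-
rate (IDR) model is deliberately **not** implemented; the reciprocal filter
stands in for it and every pipeline manifest records that substitution.
The consensus peak set concatenates the per-stage reproducible peaks, sorts,
and merges overlapping intervals (union of covered bases), then assigns
fresh sequential `peak%06d` names.

Tn5 insertion sites are derived from read 5′ ends by the standard +4 bp
(plus strand) / −5 bp (minus strand) offsets; positions that would become
negative are clipped to zero and counted (contig edges are degenerate and
rare).  Insertion coverage spreads a `width` bp window (default 30 bp,
centred) around each site and is emitted as run-length-encoded bedGraph.

## Differential accessibility

Counts per consensus peak and sample are modelled as negative binomial
(NB2) with a log link, a single categorical stage factor, and a log
library-size offset.  Because the design is one categorical factor, the
full-model maximum likelihood decomposes into independent one-dimensional
problems (one mean per stage); these are solved for all peaks
simultaneously by safeguarded bisection on the score equation
Σᵢ (yᵢ − μeᵢ)/(1 + αμeᵢ) = 0, which is strictly decreasing in μ.  A unit
test cross-checks means and log-likelihoods against statsmodels' GLM with
the NB family at fixed α.

**Dispersion.**  Per-peak dispersions α are method-of-moments estimates
(excess of the replicate variance over the Poisson part, pooled across
stages) shrunk toward a global estimate and floored at 0.01.  The global
value maximises the Cox–Reid adjusted profile likelihood summed over all
peaks — the adjustment (−½ log Fisher information per fitted stage mean)
removes the downward bias caused by estimating five means from ten
observations.  The raw per-peak estimates carry roughly one residual
degree of freedom per stage, so they receive a weight of 0.25 against the
pooled value; weighting them more heavily injects their sampling noise
into the null distribution of the test and inflates the type-I error
above nominal.  On stage-free NB simulations (α = 0.1, 5 stages × 2
replicates) the resulting likelihood-ratio test rejects at ~5% for
nominal 5%, which the acceptance suite verifies.

**Test and call.**  The likelihood ratio of stage model vs intercept-only
is referred to χ²(S−1); an F-type small-sample reference is available via
`pvalue_method="f"`.  P-values are Benjamini–Hochberg adjusted across all
peaks (not per chromosome).  Fold changes are computed from moderated
stage means (Σy + 0.5)/Σe against the first stage in the declared order
(reference coding), keeping them finite for all-zero groups.  A peak is
*dynamic* when |log₂FC| > 2 strictly and adjusted p < 0.005 strictly —
both inequalities strict, so boundary values do not pass.  A
Gaussian-on-log mode (one-way ANOVA on log₂(RPKM+1)) is provided behind
`error_model="gaussian"` as a cross-check; the NB-on-counts mode is the
default because ATAC fragment counts are overdispersed counts.

RPKM is count / (length·kb⁻¹ × library·10⁻⁶); it feeds visualisation,
trajectory construction and the Gaussian mode, while the NB test operates
on raw counts with the library-size offset.

## Temporal classification

Dynamic-peak trajectories are replicate-averaged log₂(RPKM+1) stage means,
z-scored per peak (population SD; constant rows map to all-zeros — they
cannot be dynamic anyway).  Peaks whose midpoint lies within ±2,000 bp of
any TSS are excluded beforehand as promoter-proximal; the threshold is
configurable since no canonical value exists.

Fuzzy c-means (Bezdek, Euclidean) with k = 8 and fuzzifier m = 1.25
alternates membership and centroid updates until the maximal centroid
shift falls below 10⁻⁶; the objective Σ uᵐd² is non-increasing and every
run is deterministic given the seed.  Initialisation is k-means++ seeding
on the data rows: random membership initialisation can collapse several
centroids onto one dense archetype, which k-means++ avoids.  m = 1.25 is
a common choice for standardised trajectory clustering: memberships stay
crisp enough that the maximal membership ("membership score") is a
meaningful pattern-fidelity measure.

Each of the eight centroids is assigned to the best-Pearson-correlated
member of a library of six named z-scored archetypes — ADE^OFF (closes at
the ADE transition and stays shut), VFG^OFF (opens at ADE, closes in
expansion), PE^OFF (closes only at PE), PE^ON (opens only at PE), VFG^TR
(transiently open during expansion), PE^PRIMED (monotone rise into PE).
Several centroids may share an archetype; this is exactly the 8 → 6
cluster merge.  Correlation ties break by archetype declaration order
with a warning.  The exact merge partition of the original analysis is
not published, so archetype correlation is the package's documented
reconstruction of the described shapes.

**Pairwise OPEN/CLOSE classes.**  The expansion-resolved classes
(VFGp3^OPEN/CLOSE, VFGp6^OPEN/CLOSE) re-use the NB machinery on stage
pairs (default |log₂FC| > 1, padj < 0.05 for a single transition, BH per
contrast).  "Open at a stage" uses the midpoint rule: the stage mean lies
in the upper half of the peak's own range.  A peak enters the earliest
class whose definition it satisfies, making the classes disjoint by
construction (asserted on every run).

**Cross-protocol classes.**  Against an external directed-differentiation
atlas (stages DE/FG/PP1): PE-PP1-common = (PE^PRIMED ∪ PE^ON) ∩ PP1;
PE-not-PP1 = the same minus PP1; VFG^OFF-in-DE-PP1 = VFG^OFF ∩ (DE ∪ PP1);
VFG^TR-in-PP1 = VFG^TR ∩ PP1.  These use any-overlap (≥1 bp) intersection
and the `unique_a` mode.

## Gene linking and expression sets

Each peak is linked to the single gene whose TSS is nearest its midpoint,
within a window of 25 kb or 200 kb (both windows are carried through the
pipeline; expected counts are computed separately per window).  The
window is measured from the peak midpoint — whether the original
"single nearest gene" rule anchors at the midpoint or the edge is not
stated, and midpoint is the simpler convention.  Strand only determines
which end of the gene span is the TSS.  Equidistant ties go to the
lexicographically smaller gene identifier (deterministic, warned).  This
is a deliberate simplification of GREAT's gene-centric regulatory-domain
model; only the nearest-TSS rule is reimplemented.

Differential-expression tables (gene, baseMean, log₂FC, adjusted p) are
*inputs* — no DE model is fitted here.  The gene-set filters are strict:
up = baseMean > 1,000 ∧ log₂FC > 1.5 ∧ padj < 0.05; down mirrors with
log₂FC < −1.5; missing padj excludes the gene.  Expression patterns
(condition-mean z-scores) are grouped by average-linkage Euclidean
agglomerative clustering cut at k = 10; constant rows go to a dedicated
`flat` cluster.

## Enrichment statistic

For classes × gene sets: the universe is the linked, class-labelled
peaks; observed_c is the number of class-c peaks linked to an in-set
gene; expected_c = n_c × (in-set-linked / linked-total) — the two-way
contingency expectation (row total × column total / grand total), which
makes the reported χ² coherent with the score.  The score is
log₂(observed/expected); observed = 0 yields a −∞ sentinel flagged
censored, expected = 0 a missing row.  Significance is Pearson χ² on the
2×2 table (class vs rest) × (in set vs not), 1 df, no continuity
correction; a peak-label permutation p (default 10,000 draws) is
available for small counts.  Class observed counts always sum to the
column total (asserted), and the score is invariant under duplicating
every peak and link.

For classes × H3K27ac region sets the construction is identical with
any-overlap (≥1 bp) counting against the consensus-peak universe.
Tissue sets: replicate-consistent peaks per tissue (reciprocal 50%
filter; single-replicate tissues — stomach in the study design — pass
through with a warning), tissue-unique regions (no overlap with any
other tissue, then sorted and merged so each regulatory region counts
once), and germ-layer sets built the same way on concatenated layers
(ectoderm = RPE + brain; endoderm = pancreas, liver, lung, stomach;
mesoderm = heart + adrenal).  Output tables fix the tissue axis order
P, Lv, H, A, B, R, Ln, S.

## Cluster alignment (CAT)

Cells failing QC are removed first: total UMIs and detected genes must
lie strictly inside (2,000, 35,000) and (550, 4,950) respectively, and
mitochondrial content must not exceed 20%.  Expression is library-size
log-normalised, ln(1 + 10⁴·count/total), then each gene is z-scored
across cells.  Scaling across cells (rather than across cluster
centroids) matters: genes whose between-cluster contrast is small
relative to cell-to-cell noise then contribute little to distances,
whereas centroid-level scaling would amplify pure-noise genes to unit
scale and swamp the signature signal.

The shared gene panel is the union of each dataset's top-2,000
most-variable genes intersected with the common genes (the original
alignment method's panel is not specified; this choice is logged in the
report metadata).  For each cluster, 1,000 bootstrap replicates resample
its cells with replacement and average panel expression; each cluster
has its own name-keyed RNG stream, so profiles are byte-reproducible and
independent of iteration order.

For a source cluster, Euclidean distances from its 1,000 bootstrap means
to each target centroid form per-target distance distributions, ranked
by mean.  The alignment extends to rank r (rank depth 2 by default, so
one source may align to two targets) when the rank-r distances separate
from rank r+1 by more than a margin, one-sided Welch test at α = 0.01.
The margin defaults to 0.25 × the median inter-cluster mean distance: a
scale-free gap requirement.  A zero margin is statistically degenerate
here — with 1,000 bootstrap replicates the Welch test resolves arbitrarily
small ordering differences, so every cluster would acquire a "significant"
nearest partner, related or not.  The criterion (α, margin, rank depth)
is an implementation decision recorded in the output metadata, not a
claim about the original method's unpublished rule.  Alignment is
directional (A→B); mutual nearest pairs are flagged.

## Synthetic data

The generators produce every input the pipeline consumes, with planted
ground truth, at the study's own conditions: 5 stages × 2 replicates;
six archetype groups × 500 peaks plus 2,000 static peaks; NB dispersion
0.1; an 8-fold accessibility range between closed and open states;
peak widths 200–1,000 bp placed without overlap on a 2 × 10 Mb synthetic
genome (uniform placement by stick-breaking); library sizes ~10⁷.
Planted target genes sit 2.5–12 kb from their peak midpoints (outside
the promoter filter, inside the 25 kb window) for 35% of classified
peaks; noise genes are scattered uniformly.  DE tables give genes linked
to priming/opening classes (PE^PRIMED, PE^ON) log₂FC ≈ +2, genes linked
to decommissioned classes (PE^OFF, VFG^TR) ≈ −2, and null statistics to
everything else.  Single-cell data comprise two datasets of 5 clusters
× 100 cells over 1,500 genes (10 mitochondrial), 30-gene signature
programs at 8-fold elevation, 3 of 5 programs shared across datasets,
plus planted high-mito and low-depth cells for the QC filters.

**Fold calibration.**  The observed/expected statistic measures a class
against the pooled dataset rate, which includes the enriched class
itself.  A naive hit rate of fold × background therefore realizes less
than the intended fold.  The tissue-overlap and gene-set generators
solve p = r·N_bg/(N − Σ n_c f_c) for the pooled rate p and plant class
rates f_c·p, so the *realized* observed/expected equals the configured
fold.  Rates that would exceed 0.95 are capped with a warning (the
requested folds are then infeasible for the class sizes).

All generators draw from named RNG streams derived from one seed
(`default_rng([seed, crc32(stream)])`), so adding a generator never
perturbs the others and equal seeds give byte-identical outputs.

**What passing tests do not show.**  The synthetic data have idealised
properties real data lack: equal class sizes, a common dispersion, clean
archetype shapes, no GC or copy-number structure, no fragment-length
biology, no doublets or ambient RNA, and genes placed independently of
chromatin domains.  Recovery rates measured here (sensitivity ≈ 0.99,
group agreement ≈ 0.999 at these settings) are upper bounds on real-data
performance; what the tests certify is the correctness and calibration
of the machinery, not field performance.

## Numerical choices and degenerate inputs

- NB group-mean solver: 60 bisection iterations on [10⁻¹², 2·max(y/e)+1];
  all-zero groups pin μ to 10⁻¹² with log-likelihood contribution 0.
- Dispersion bounds for the global Cox–Reid estimate: [10⁻³, 3].
- c-means: distances floored at 10⁻³⁰⁰ for the membership ratio; exact
  zero distances give full membership on the coincident centroid(s);
  non-convergence at `max_iter` returns with a warning flag.
- Constant trajectory rows z-score to zeros; constant expression rows go
  to the `flat` cluster.
- padj is reported as max(BH, raw p) so adjusted values never undercut
  raw ones.
- All output tables are written with `%.6g` float formatting, and the run
  manifest stores the seed, every threshold, and SHA-256 checksums of all
  inputs, making rerun equality checkable by hashing the workspace.

## Problem sizes

Default analysis and test sizes (5,000 peaks, 10 samples, 1,000 cells per
single-cell dataset, 1,000 bootstrap replicates) complete in tens of
seconds on one CPU; the vectorised NB solver and the matrix-level
bootstrap are what keep the stage test and CAT inexpensive at these
scales.  These sizes were chosen as the smallest at which the planted
effects and calibration checks are statistically stable.

## Known limitations

- The reciprocal-overlap filter is a stand-in for IDR; it has no
  irreproducibility FDR semantics.
- The NB test models a single stage factor; no covariates, no
  interaction terms, no trended dispersion.
- Nearest-TSS linking ignores topological domains and enhancer skipping;
  the 25/200 kb windows inherit that simplification.
- The CAT significance rule is a documented in-package criterion; the
  original method's rule is defined elsewhere and may differ.
- The promoter-distal threshold (±2 kb) and the archetype library encode
  reasonable but not unique choices; both are configurable.
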