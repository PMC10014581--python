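"""Temporal chromatin-accessibility dynamics across a differentiation
time course.

The substrate is a peak x sample count matrix over an ordered set of
stages (default ESC -> ADE -> VFGp3 -> VFGp6 -> PE) with >=2 replicates
per stage.  Peaks with stage-dependent accessibility are detected with a
negative-binomial log-link model (stage factor, log library-size offset,
fixed per-peak dispersion) tested by likelihood ratio against an
intercept-only model.  Dynamic trajectories are z-scored, soft-clustered
by fuzzy c-means, and each cluster centroid is matched to a named
temporal archetype, merging similar clusters into the six canonical
enhancer groups.

Because the design matrix contains a single categorical factor, the
full-model NB maximum likelihood decomposes into independent one-
dimensional problems (one mean per stage), which are solved for all
peaks at once by safeguarded bisection on the score equation.  A test
cross-checks this solver against statsmodels' GLM on small instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .intervals import PeakAtlas, intersect, intersect_any, union_atlas

__all__ = [
    "AccessibilityMatrix",
    "read_counts_tsv",
    "read_sample_sheet",
    "rpkm_normalize",
    "detect_dynamic_peaks",
    "stage_pair_test",
    "dynamic_rule",
    "standardize_trajectories",
    "cmeans_cluster",
    "CmeansResult",
    "assign_groups",
    "pairwise_open_close",
    "cross_protocol_classes",
    "DEFAULT_ARCHETYPES",
    "GROUP_NAMES",
]

GROUP_NAMES = ("ADE^OFF", "VFG^OFF", "PE^OFF", "PE^ON", "VFG^TR", "PE^PRIMED")

#: Raw stage-profiles (before z-scoring) of the six temporal archetypes over
#: the canonical five stages.  Shapes: ADE^OFF closes at the first transition
#: and stays shut; VFG^OFF opens at ADE then closes during expansion; PE^OFF
#: closes only at PE; PE^ON opens only at PE; VFG^TR peaks during expansion
#: then shuts; PE^PRIMED rises monotonically into PE.
DEFAULT_ARCHETYPES: dict[str, np.ndarray] = {
    "ADE^OFF": np.array([1.0, 0.0, 0.0, 0.0, 0.0]),
    "VFG^OFF": np.array([0.0, 1.0, 0.1, 0.0, 0.0]),
    "PE^OFF": np.array([0.0, 1.0, 1.0, 1.0, 0.0]),
    "PE^ON": np.array([0.0, 0.0, 0.0, 0.0, 1.0]),
    "VFG^TR": np.array([0.0, 0.2, 1.0, 1.0, 0.0]),
    "PE^PRIMED": np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
}


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------


@dataclass
class AccessibilityMatrix:
    """Peak x sample counts with sample metadata and the peak atlas.

    ``samples`` must be indexed by sample name with columns ``stage``,
    ``replicate`` and ``library_size``; ``stage_order`` fixes the temporal
    ordering (first stage is the fold-change reference).
    """

    counts: pd.DataFrame
    atlas: PeakAtlas
    samples: pd.DataFrame
    stage_order: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [p for p in self.counts.index if p not in self.atlas.id_index]
        if missing:
            raise ValueError(f"peaks absent from atlas: {missing[:3]} ...")
        if list(self.counts.columns) != list(self.samples.index):
            self.samples = self.samples.loc[self.counts.columns]
        stages = set(self.samples["stage"])
        if not stages.issubset(self.stage_order):
            raise ValueError("sample sheet contains stages outside stage_order")
        present = [s for s in self.stage_order if s in stages]
        if len(present) < 2:
            raise ValueError("need >=2 stages")
        self.stage_order = tuple(present)
        if (self.samples["library_size"] <= 0).any():
            raise ValueError("library_size must be > 0")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def peak_lengths(self) -> pd.Series:
        return pd.Series(
            {p: self.atlas.id_index[p].length for p in self.counts.index},
            name="length",
        )

    def stage_of(self) -> pd.Series:
        return self.samples["stage"]

    def replicates_per_stage(self) -> pd.Series:
        return self.samples.groupby("stage").size()


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "stage", "replicate", "library_size"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return df.set_index("sample")


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


def rpkm_normalize(m: AccessibilityMatrix) -> pd.DataFrame:
    """Reads per kilobase per million: count / (length_kb * libsize_millions)."""
    lengths = m.peak_lengths
    if (lengths <= 0).any():
        raise ValueError("zero-length peak")
    len_kb = lengths.values[:, None] / 1000.0
    lib_m = m.samples["library_size"].values[None, :] / 1e6
    return pd.DataFrame(
        m.counts.values / (len_kb * lib_m),
        index=m.counts.index,
        columns=m.counts.columns,
    )


# ---------------------------------------------------------------------------
# Negative-binomial group model (vectorised)
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of the NB2 log-likelihood; y, mean: (P, n); alpha: (P, 1)."""
    r = 1.0 / alpha
    mean = np.maximum(mean, 1e-12)
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mean))
        + y * np.log(mean / (r + mean))
    )
    # y == 0 and mean -> 0 gives 0 * log(0) = nan above; the limit is 0
    ll = np.where((y == 0) & (mean <= 1e-12), 0.0, ll)
    return ll.sum(axis=1)


def _nb_group_mean_mle(
    y: np.ndarray, exposure: np.ndarray, alpha: np.ndarray, n_iter: int = 60
) -> np.ndarray:
    """MLE of the NB mean rate mu for each peak over one sample group.

    Solves sum_i (y_i - mu e_i) / (1 + alpha mu e_i) = 0 (score equation of
    the log-link NB with offset log e) by bisection; the score is strictly
    decreasing in mu.  y: (P, n); exposure: (n,); alpha: (P,).  Returns (P,).
    """
    e = exposure[None, :]
    a = alpha[:, None]
    lo = np.full(y.shape[0], 1e-12)
    hi = (y / e).max(axis=1) * 2.0 + 1.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        score = ((y - mid[:, None] * e) / (1.0 + a * mid[:, None] * e)).sum(axis=1)
        go_up = score > 0
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
    mu = 0.5 * (lo + hi)
    return np.where(y.sum(axis=1) == 0, 1e-12, mu)


def _cr_global_dispersion(
    counts: np.ndarray,
    exposure: np.ndarray,
    group_idx: np.ndarray,
    bounds: tuple[float, float] = (1e-3, 3.0),
) -> float:
    """Global NB dispersion by Cox-Reid adjusted profile likelihood.

    Maximises the summed profile log-likelihood over all peaks (group
    means profiled out by their MLE) minus half the log Fisher
    information of each fitted log-mean — the adjustment that removes the
    downward bias caused by estimating one mean per stage from few
    replicates.
    """
    from scipy.optimize import minimize_scalar

    if counts.sum() == 0:
        return bounds[0]
    n_groups = group_idx.max() + 1
    cols_by_group = [np.where(group_idx == g)[0] for g in range(n_groups)]

    def neg_apl(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        a = np.full(counts.shape[0], alpha)
        mu_full = np.empty_like(counts, dtype=float)
        adj = np.zeros(counts.shape[0])
        for cols in cols_by_group:
            mu = _nb_group_mean_mle(counts[:, cols], exposure[cols], a)
            mean = mu[:, None] * exposure[cols][None, :]
            mu_full[:, cols] = mean
            info = (mean / (1.0 + alpha * mean)).sum(axis=1)
            adj += 0.5 * np.log(np.maximum(info, 1e-12))
        ll = _nb_loglik(counts, mu_full, a[:, None])
        return -float((ll - adj).sum())

    res = minimize_scalar(
        neg_apl,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def estimate_dispersions(
    counts: np.ndarray,
    exposure: np.ndarray,
    group_idx: np.ndarray,
    floor: float = 0.01,
    shrink: float = 0.25,
) -> np.ndarray:
    """Per-peak NB dispersion: method-of-moments estimates shrunk toward a
    Cox-Reid global profile-likelihood estimate, floored at ``floor``.

    Within each stage the normalised counts y/e have approximate variance
    mu/e + alpha mu^2; the excess of the replicate variance over the
    Poisson part gives the raw per-peak estimate.  With only a couple of
    replicates per stage the raw estimates carry ~1 residual df per stage,
    so they receive a small weight (``shrink``, default 0.25) against the
    pooled estimate; weighting them more strongly injects their sampling
    noise into the null distribution of the stage test.
    """
    n_groups = group_idx.max() + 1
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    for g in range(n_groups):
        cols = np.where(group_idx == g)[0]
        if len(cols) < 2:
            continue
        yn = counts[:, cols] / exposure[cols][None, :]
        m = yn.mean(axis=1)
        v = yn.var(axis=1, ddof=1)
        pois = m / exposure[cols].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            a_g = (v - pois) / np.maximum(m, 1e-12) ** 2
        ok = m > 0
        num[ok] += np.clip(a_g[ok], 0.0, 10.0) * (len(cols) - 1)
        den[ok] += len(cols) - 1
    raw = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    pooled = _cr_global_dispersion(counts, exposure, group_idx)
    return np.maximum(shrink * raw + (1 - shrink) * pooled, floor)


def dynamic_rule(
    log2fc_max: np.ndarray | pd.Series,
    padj: np.ndarray | pd.Series,
    lfc_threshold: float = 2.0,
    padj_threshold: float = 0.005,
) -> np.ndarray:
    """The dynamic-peak call: |log2FC| strictly above the fold threshold AND
    adjusted p strictly below the significance threshold."""
    return (np.abs(np.asarray(log2fc_max)) > lfc_threshold) & (
        np.asarray(padj) < padj_threshold
    )


def _nb_stage_test(
    counts: np.ndarray,
    exposure: np.ndarray,
    group_idx: np.ndarray,
    alpha: np.ndarray,
    pvalue_method: str = "chisq",
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio test of the stage factor; returns (pvalue, log2fc per group).

    log2 fold changes are computed from moderated group means
    (sum(y)+0.5)/(sum(e)) against the first group (reference coding), which
    keeps them finite for all-zero groups.
    """
    n_groups = group_idx.max() + 1
    n = counts.shape[1]
    mu_full = np.empty((counts.shape[0], n))
    mod_means = np.empty((counts.shape[0], n_groups))
    for g in range(n_groups):
        cols = np.where(group_idx == g)[0]
        mu_g = _nb_group_mean_mle(counts[:, cols], exposure[cols], alpha)
        mu_full[:, cols] = mu_g[:, None] * exposure[cols][None, :]
        mod_means[:, g] = (counts[:, cols].sum(axis=1) + 0.5) / exposure[cols].sum()
    mu_null = _nb_group_mean_mle(counts, exposure, alpha)
    ll_full = _nb_loglik(counts, mu_full, alpha[:, None])
    ll_null = _nb_loglik(counts, mu_null[:, None] * exposure[None, :], alpha[:, None])
    lr = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    df = n_groups - 1
    if pvalue_method == "chisq":
        pval = stats.chi2.sf(lr, df)
    elif pvalue_method == "f":
        # small-sample reference: LR/df against F(df, n - n_groups)
        pval = stats.f.sf(lr / df, df, max(n - n_groups, 1))
    else:
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    log2fc = np.log2(mod_means / mod_means[:, [0]])
    allzero = counts.sum(axis=1) == 0
    pval = np.where(allzero, 1.0, pval)
    log2fc[allzero] = 0.0
    return pval, log2fc


def _groups_from_samples(
    samples: pd.DataFrame, stage_order: Sequence[str]
) -> np.ndarray:
    stage_pos = {s: i for i, s in enumerate(stage_order)}
    return samples["stage"].map(stage_pos).to_numpy()


def detect_dynamic_peaks(
    m: AccessibilityMatrix,
    lfc_threshold: float = 2.0,
    padj_threshold: float = 0.005,
    error_model: str = "nb",
    pvalue_method: str = "chisq",
) -> pd.DataFrame:
    """Per-peak test for stage-dependent accessibility.

    Returns a DataFrame indexed by peak with columns ``log2fc_max`` (signed
    largest stage-vs-reference fold change), ``pvalue``, ``padj``
    (Benjamini-Hochberg over all peaks) and ``is_dynamic``.

    ``error_model="nb"`` (default) fits the negative-binomial model on raw
    counts with a log library-size offset; ``error_model="gaussian"`` runs
    one-way ANOVA on log2(RPKM+1) as a cross-check mode.
    """
    if (m.replicates_per_stage() < 2).any():
        raise ValueError("the stage test requires >=2 replicates per stage")
    group_idx = _groups_from_samples(m.samples, m.stage_order)
    counts = m.counts.to_numpy(dtype=float)
    if error_model == "nb":
        exposure = m.samples["library_size"].to_numpy(dtype=float) / 1e7
        alpha = estimate_dispersions(counts, exposure, group_idx)
        pval, log2fc = _nb_stage_test(
            counts, exposure, group_idx, alpha, pvalue_method
        )
    elif error_model == "gaussian":
        logn = np.log2(rpkm_normalize(m).to_numpy() + 1.0)
        pval, log2fc = _gaussian_stage_test(logn, group_idx)
        pval = np.where(counts.sum(axis=1) == 0, 1.0, pval)
    else:
        raise ValueError(f"unknown error_model {error_model!r}")
    idx_max = np.abs(log2fc[:, 1:]).argmax(axis=1) + 1
    lfc_max = log2fc[np.arange(log2fc.shape[0]), idx_max]
    lfc_max = np.where(counts.sum(axis=1) == 0, 0.0, lfc_max)
    padj = multipletests(pval, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2fc_max": lfc_max,
            "pvalue": pval,
            "padj": np.maximum(padj, pval),
            "is_dynamic": dynamic_rule(lfc_max, padj, lfc_threshold, padj_threshold),
        },
        index=m.counts.index,
    )
    return out


def _gaussian_stage_test(
    values: np.ndarray, group_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA across stage groups on transformed values."""
    n_groups = group_idx.max() + 1
    n = values.shape[1]
    grand = values.mean(axis=1)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    means = np.empty((values.shape[0], n_groups))
    for g in range(n_groups):
        cols = np.where(group_idx == g)[0]
        mg = values[:, cols].mean(axis=1)
        means[:, g] = mg
        ssb += len(cols) * (mg - grand) ** 2
        ssw += ((values[:, cols] - mg[:, None]) ** 2).sum(axis=1)
    df1, df2 = n_groups - 1, n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / np.maximum(ssw / df2, 1e-300)
    pval = stats.f.sf(f, df1, df2)
    pval = np.where(ssw + ssb < 1e-300, 1.0, pval)
    log2fc = means - means[:, [0]]  # already log2 scale
    return pval, log2fc


def stage_pair_test(
    m: AccessibilityMatrix,
    stage_a: str,
    stage_b: str,
    pvalue_method: str = "chisq",
) -> pd.DataFrame:
    """NB likelihood-ratio test between two stages.

    Returns DataFrame (peak x [log2fc, pvalue, padj]) where log2fc is
    stage_b versus stage_a.
    """
    keep = m.samples["stage"].isin([stage_a, stage_b])
    sub = m.samples.loc[keep]
    counts = m.counts.loc[:, sub.index].to_numpy(dtype=float)
    group_idx = (sub["stage"] == stage_b).to_numpy().astype(int)
    exposure = sub["library_size"].to_numpy(dtype=float) / 1e7
    alpha = estimate_dispersions(counts, exposure, group_idx)
    pval, log2fc = _nb_stage_test(counts, exposure, group_idx, alpha, pvalue_method)
    padj = multipletests(pval, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc[:, 1], "pvalue": pval, "padj": np.maximum(padj, pval)},
        index=m.counts.index,
    )


# ---------------------------------------------------------------------------
# Trajectories and fuzzy c-means
# ---------------------------------------------------------------------------


def stage_mean_log_signal(
    normalized: pd.DataFrame, samples: pd.DataFrame, stage_order: Sequence[str]
) -> pd.DataFrame:
    """Replicate-averaged log2(RPKM+1) per stage (peak x stage)."""
    logn = np.log2(normalized + 1.0)
    cols = {}
    for stage in stage_order:
        samp = samples.index[samples["stage"] == stage]
        cols[stage] = logn[samp].mean(axis=1)
    return pd.DataFrame(cols)[list(stage_order)]


def standardize_trajectories(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    stage_order: Sequence[str],
    dynamic: pd.Series | None = None,
) -> pd.DataFrame:
    """Z-score each peak's stage-mean trajectory (population sd).

    Constant rows become all-zero rows (they carry no temporal shape and
    cannot be dynamic in any case).  If ``dynamic`` is given, only flagged
    peaks are kept.
    """
    means = stage_mean_log_signal(normalized, samples, stage_order)
    if dynamic is not None:
        means = means.loc[dynamic.reindex(means.index, fill_value=False)]
    vals = means.to_numpy()
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    z = np.where(sd > 1e-12, (vals - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=means.index, columns=means.columns)


@dataclass
class CmeansResult:
    """Fuzzy c-means output: soft memberships, hard labels and centroids."""

    membership: pd.DataFrame  # peak x cluster (columns 1..k), rows sum to 1
    centroids: pd.DataFrame  # cluster x stage
    hard_cluster: pd.Series  # peak -> argmax cluster id
    membership_score: pd.Series  # peak -> max membership
    objective: list[float] = field(default_factory=list)
    converged: bool = True
    group: pd.Series | None = None  # filled by assign_groups
    cluster_to_group: dict[int, str] | None = None


def cmeans_cluster(
    trajectories: pd.DataFrame,
    k: int = 8,
    fuzzifier_m: float = 1.25,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> CmeansResult:
    """Standard (Bezdek) fuzzy c-means with Euclidean distance.

    Alternates membership and centroid updates from a random initial
    membership matrix until the maximal centroid shift falls below ``tol``.
    The objective sum_ij u_ij^m d_ij^2 is non-increasing; deterministic
    given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = trajectories.to_numpy(dtype=float)
    n = x.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    rng = np.random.default_rng(seed)
    expo = 1.0 / (fuzzifier_m - 1.0)
    # k-means++ seeding, then memberships from the seed centroids; far more
    # robust than random memberships, which can collapse several centroids
    # onto one dense archetype
    seeds = [int(rng.integers(n))]
    closest = ((x - x[seeds[0]]) ** 2).sum(axis=1)
    for _ in range(1, k):
        prob = closest / max(closest.sum(), 1e-300)
        seeds.append(int(rng.choice(n, p=prob)))
        closest = np.minimum(closest, ((x - x[seeds[-1]]) ** 2).sum(axis=1))
    init = x[seeds]
    d2 = np.maximum(((x[:, None, :] - init[None, :, :]) ** 2).sum(axis=2), 1e-300)
    u = (d2 / d2.min(axis=1, keepdims=True)) ** (-expo)
    u /= u.sum(axis=1, keepdims=True)
    objective: list[float] = []
    centroids = np.zeros((k, x.shape[1]))
    converged = False
    for _ in range(max_iter):
        um = u**fuzzifier_m
        new_centroids = (um.T @ x) / np.maximum(um.sum(axis=0)[:, None], 1e-300)
        d2 = ((x[:, None, :] - new_centroids[None, :, :]) ** 2).sum(axis=2)
        d2c = np.maximum(d2, 1e-300)
        ratio = d2c / d2c.min(axis=1, keepdims=True)
        u_new = ratio ** (-expo)
        # exact-zero distances: all mass on the coincident centroid(s)
        zero = d2 < 1e-12
        rows_zero = zero.any(axis=1)
        u_new[rows_zero] = zero[rows_zero].astype(float)
        u_new /= u_new.sum(axis=1, keepdims=True)
        objective.append(float(((u_new**fuzzifier_m) * d2).sum()))
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        u = u_new
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"fuzzy c-means did not converge in {max_iter} iterations")
    cluster_ids = list(range(1, k + 1))
    memb = pd.DataFrame(u, index=trajectories.index, columns=cluster_ids)
    hard = pd.Series(
        np.asarray(cluster_ids)[u.argmax(axis=1)], index=trajectories.index
    )
    return CmeansResult(
        membership=memb,
        centroids=pd.DataFrame(centroids, index=cluster_ids, columns=trajectories.columns),
        hard_cluster=hard,
        membership_score=pd.Series(u.max(axis=1), index=trajectories.index),
        objective=objective,
        converged=converged,
    )


def _zscore_profile(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 1e-12 else np.zeros_like(v)


def assign_groups(
    result: CmeansResult,
    archetypes: Mapping[str, np.ndarray] | None = None,
) -> CmeansResult:
    """Match each c-means centroid to the best-correlated named archetype.

    Several centroids may map to the same group — this is the merge of the
    eight raw clusters into the six named enhancer groups.  Correlation ties
    break deterministically by archetype declaration order (with a warning).
    Returns the result with ``group`` and ``cluster_to_group`` filled.
    """
    if archetypes is None:
        archetypes = DEFAULT_ARCHETYPES
    names = list(archetypes)
    profs = np.stack([_zscore_profile(np.asarray(archetypes[g], float)) for g in names])
    if profs.shape[1] != result.centroids.shape[1]:
        raise ValueError("archetype length does not match number of stages")
    mapping: dict[int, str] = {}
    for cid, centroid in result.centroids.iterrows():
        c = _zscore_profile(centroid.to_numpy())
        with np.errstate(invalid="ignore"):
            corrs = np.array(
                [np.corrcoef(c, p)[0, 1] if p.any() and c.any() else -1.0 for p in profs]
            )
        corrs = np.nan_to_num(corrs, nan=-1.0)
        best = float(corrs.max())
        winners = [names[i] for i in range(len(names)) if np.isclose(corrs[i], best)]
        if len(winners) > 1:
            warnings.warn(
                f"correlation tie for cluster {cid}: {winners}; "
                "taking first in archetype order"
            )
        mapping[int(cid)] = winners[0]
    result.cluster_to_group = mapping
    result.group = result.hard_cluster.map(mapping)
    return result


# ---------------------------------------------------------------------------
# Pairwise OPEN/CLOSE classes and cross-protocol set algebra
# ---------------------------------------------------------------------------


def pairwise_open_close(
    m: AccessibilityMatrix,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
) -> pd.Series:
    """Classify peaks by the first expansion transition they respond to.

    With stages (s0, s1, s2, s3, ...) the classes are built on the two
    transitions s1->s2 and s2->s3 (e.g. ADE->VFGp3 and VFGp3->VFGp6):

    * ``s2^OPEN``  — significant gain s1->s2, not already open at s0 or s1;
    * ``s2^CLOSE`` — open at s1, significant loss s1->s2;
    * ``s3^OPEN``  — significant gain s2->s3, not open at any earlier stage;
    * ``s3^CLOSE`` — open at s2, significant loss s2->s3.

    A peak enters the earliest class whose definition it satisfies; the
    classes are mutually exclusive by construction.  "Open at a stage" means
    the stage-mean log signal lies in the upper half of the peak's own range
    (midpoint rule).
    """
    so = m.stage_order
    if len(so) < 4:
        raise ValueError("pairwise classification needs >=4 ordered stages")
    s0, s1, s2, s3 = so[0], so[1], so[2], so[3]
    norm = rpkm_normalize(m)
    means = stage_mean_log_signal(norm, m.samples, so)
    rng_lo = means.min(axis=1)
    rng_hi = means.max(axis=1)
    midpoint = (rng_lo + rng_hi) / 2.0
    informative = (rng_hi - rng_lo) > 1e-9
    open_at = means.gt(midpoint, axis=0) & informative.to_numpy()[:, None]

    t12 = stage_pair_test(m, s1, s2)
    t23 = stage_pair_test(m, s2, s3)
    sig_gain_12 = dynamic_rule(t12["log2fc"], t12["padj"], lfc_threshold, padj_threshold) & (
        t12["log2fc"] > 0
    )
    sig_loss_12 = dynamic_rule(t12["log2fc"], t12["padj"], lfc_threshold, padj_threshold) & (
        t12["log2fc"] < 0
    )
    sig_gain_23 = dynamic_rule(t23["log2fc"], t23["padj"], lfc_threshold, padj_threshold) & (
        t23["log2fc"] > 0
    )
    sig_loss_23 = dynamic_rule(t23["log2fc"], t23["padj"], lfc_threshold, padj_threshold) & (
        t23["log2fc"] < 0
    )

    cls = pd.Series("none", index=m.counts.index, dtype=object)
    c_open2 = sig_gain_12 & ~open_at[s0] & ~open_at[s1]
    c_close2 = sig_loss_12 & open_at[s1]
    c_open3 = sig_gain_23 & ~open_at[s0] & ~open_at[s1] & ~open_at[s2]
    c_close3 = sig_loss_23 & open_at[s2]
    # earliest class wins
    cls[c_close3] = f"{s3}^CLOSE"
    cls[c_open3] = f"{s3}^OPEN"
    cls[c_close2] = f"{s2}^CLOSE"
    cls[c_open2] = f"{s2}^OPEN"
    assert (
        (c_open2 & c_close2).sum() == 0
    ), "pairwise OPEN/CLOSE classes must be disjoint"
    return cls


def cross_protocol_classes(
    own_class_atlases: Mapping[str, PeakAtlas],
    external_accessible: Mapping[str, PeakAtlas],
) -> dict[str, PeakAtlas]:
    """Compare in-house enhancer classes against a directed-differentiation
    accessibility atlas (stages DE / FG / PP1).

    * ``PE-PP1-common``      — PE-accessible elements (PE^PRIMED u PE^ON)
      also accessible at the pancreatic-progenitor stage (PP1);
    * ``PE-not-PP1``         — PE-accessible elements never open in PP1;
    * ``VFG^OFF-in-DE-PP1``  — elements decommissioned during expansion that
      remain accessible in DE or PP1;
    * ``VFG^TR-in-PP1``      — transient expansion elements still open in PP1.
    """
    for key in ("PE^PRIMED", "PE^ON", "VFG^OFF", "VFG^TR"):
        if key not in own_class_atlases:
            raise KeyError(f"missing class atlas {key!r}")
    for key in ("DE", "PP1"):
        if key not in external_accessible:
            raise KeyError(f"missing external stage atlas {key!r}")
    pe_accessible = union_atlas(
        [own_class_atlases["PE^PRIMED"], own_class_atlases["PE^ON"]]
    )
    pp1 = external_accessible["PP1"]
    de_pp1 = union_atlas([external_accessible["DE"], pp1])
    return {
        "PE-PP1-common": intersect_any(pe_accessible, pp1),
        "PE-not-PP1": intersect(pe_accessible, pp1, mode="unique_a"),
        "VFG^OFF-in-DE-PP1": intersect_any(own_class_atlases["VFG^OFF"], de_pp1),
        "VFG^TR-in-PP1": intersect_any(own_class_atlases["VFG^TR"], pp1),
    }
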