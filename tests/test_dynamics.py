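"""Normalisation, the NB stage test (with statsmodels as independent
oracle), trajectory z-scoring, fuzzy c-means and class assignment."""

import numpy as np
import pandas as pd
import pytest

from enhdyn.dynamics import (
    DEFAULT_ARCHETYPES,
    _nb_group_mean_mle,
    _nb_loglik,
    assign_groups,
    cmeans_cluster,
    cross_protocol_classes,
    detect_dynamic_peaks,
    dynamic_rule,
    pairwise_open_close,
    rpkm_normalize,
    stage_pair_test,
    standardize_trajectories,
)
from enhdyn.intervals import GenomicInterval, PeakAtlas

from conftest import make_atlas, make_matrix


def test_rpkm_direct_formula():
    m = make_matrix({"p1": {"A": [10, 10], "B": [0, 0]}}, length=500, libsize=1_000_000)
    norm = rpkm_normalize(m)
    assert norm.loc["p1", "A_rep1"] == pytest.approx(10 / (0.5 * 1.0))
    assert norm.loc["p1", "B_rep1"] == 0.0


def test_rpkm_library_size_scaling():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 200, size=(20, 4))
    m = make_matrix(
        {f"p{i}": {"A": counts[i, :2].tolist(), "B": counts[i, 2:].tolist()} for i in range(20)}
    )
    norm1 = rpkm_normalize(m)
    m.samples["library_size"] *= 2.0
    norm2 = rpkm_normalize(m)
    assert np.allclose(norm2.values, norm1.values / 2.0)


def test_nb_mle_and_loglik_match_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(0)
    y = rng.poisson(rng.gamma(10, 5, size=(4, 6))).astype(float)
    e = rng.uniform(0.8, 1.2, 6)
    alpha = np.full(4, 0.12)
    mu = _nb_group_mean_mle(y, e, alpha)
    ll = _nb_loglik(y, mu[:, None] * e[None, :], alpha[:, None])
    for i in range(4):
        fit = sm.GLM(
            y[i],
            np.ones((6, 1)),
            family=sm.families.NegativeBinomial(alpha=0.12),
            offset=np.log(e),
        ).fit()
        assert mu[i] == pytest.approx(float(np.exp(fit.params[0])), rel=1e-5)
        assert ll[i] == pytest.approx(float(fit.llf), abs=1e-5)


def test_detect_dynamic_planted_fold_change():
    """An 8-fold opening between the first and last stage is detected with
    high probability at dispersion 0.1 and two replicates per stage."""
    rng = np.random.default_rng(42)
    n = 200
    stages = ["ESC", "ADE", "VFGp3", "VFGp6", "PE"]
    counts = {}
    for i in range(n):
        base = rng.uniform(50, 200)
        row = {}
        for si, st in enumerate(stages):
            mean = base * (8.0 if st == "PE" else 1.0)
            lam = rng.gamma(10.0, mean * 0.1, size=2)  # dispersion 0.1
            row[st] = rng.poisson(lam).tolist()
        counts[f"p{i}"] = row
    m = make_matrix(counts, stage_order=stages)
    dyn = detect_dynamic_peaks(m)
    assert dyn["is_dynamic"].mean() >= 0.9
    assert (dyn["log2fc_max"][dyn.is_dynamic] > 0).all()


def test_all_zero_peak_is_never_dynamic():
    stages = ["A", "B"]
    counts = {"z": {"A": [0, 0], "B": [0, 0]}}
    counts.update({f"p{i}": {"A": [50, 60], "B": [55, 45]} for i in range(5)})
    m = make_matrix(counts, stage_order=stages)
    dyn = detect_dynamic_peaks(m)
    assert dyn.loc["z", "pvalue"] == 1.0
    assert dyn.loc["z", "log2fc_max"] == 0.0
    assert not dyn.loc["z", "is_dynamic"]


def test_dynamic_rule_thresholds_are_strict():
    flags = dynamic_rule(
        np.array([2.0, 2.1, 2.1, -2.1]), np.array([0.004, 0.005, 0.004, 0.004])
    )
    assert flags.tolist() == [False, False, True, True]


def test_gaussian_mode_matches_scipy_anova():
    from scipy.stats import f_oneway

    rng = np.random.default_rng(9)
    counts = {
        f"p{i}": {st: rng.integers(10, 400, size=2).tolist() for st in ["A", "B", "C"]}
        for i in range(12)
    }
    m = make_matrix(counts, stage_order=["A", "B", "C"])
    dyn = detect_dynamic_peaks(m, error_model="gaussian")
    logn = np.log2(rpkm_normalize(m) + 1.0)
    for peak in list(counts)[:5]:
        groups = [
            logn.loc[peak, [f"{st}_rep1", f"{st}_rep2"]].to_numpy() for st in ["A", "B", "C"]
        ]
        assert dyn.loc[peak, "pvalue"] == pytest.approx(f_oneway(*groups).pvalue, rel=1e-9)


def test_standardize_trajectories_properties():
    rng = np.random.default_rng(2)
    counts = {
        "inc": {st: [v, v] for st, v in zip("ABCDE", [10, 40, 90, 160, 250])},
        "flat": {st: [30, 30] for st in "ABCDE"},
    }
    for i in range(10):
        counts[f"r{i}"] = {st: rng.integers(5, 500, size=2).tolist() for st in "ABCDE"}
    m = make_matrix(counts, stage_order=list("ABCDE"))
    traj = standardize_trajectories(rpkm_normalize(m), m.samples, list("ABCDE"))
    assert np.allclose(traj.mean(axis=1), 0.0, atol=1e-12)
    inc = traj.loc["inc"].to_numpy()
    assert np.all(np.diff(inc) > 0) and np.isclose(inc.std(), 1.0)
    assert np.allclose(traj.loc["flat"], 0.0)
    nonflat = traj.drop(index="flat")
    assert np.allclose(nonflat.std(axis=1, ddof=0), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------


def test_cmeans_planted_two_archetypes():
    rng = np.random.default_rng(0)
    a, b = np.array([1.0, 0, 0, 0, 1.0]), np.array([0, 1.0, 1.0, 1.0, 0])
    rows = np.vstack(
        [a + rng.normal(0, 0.05, size=(200, 5)), b + rng.normal(0, 0.05, size=(200, 5))]
    )
    traj = pd.DataFrame(rows, index=[f"p{i}" for i in range(400)], columns=list("ABCDE"))
    res = cmeans_cluster(traj, k=2, seed=0)
    assert res.converged
    strong = res.membership_score > 0.9
    assert strong.mean() >= 0.99
    first = res.hard_cluster.iloc[:200].mode()[0]
    second = res.hard_cluster.iloc[200:].mode()[0]
    assert first != second
    assert (res.hard_cluster.iloc[:200] == first).mean() >= 0.99
    # memberships: rows sum to 1, scores within [1/k, 1]
    assert np.allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)
    assert ((res.membership_score >= 0.5 - 1e-9) & (res.membership_score <= 1.0)).all()


def test_cmeans_objective_non_increasing():
    rng = np.random.default_rng(3)
    traj = pd.DataFrame(rng.normal(size=(150, 5)))
    res = cmeans_cluster(traj, k=4, seed=1)
    obj = np.array(res.objective)
    assert np.all(np.diff(obj) <= 1e-9)


def test_cmeans_equidistant_row_gets_uniform_membership():
    rng = np.random.default_rng(4)
    a, b = np.array([2.0, 0.0]), np.array([-2.0, 0.0])
    rows = np.vstack(
        [
            a + rng.normal(0, 0.01, size=(50, 2)),
            b + rng.normal(0, 0.01, size=(50, 2)),
            np.zeros((1, 2)),  # equidistant from both centroids
        ]
    )
    traj = pd.DataFrame(rows)
    res = cmeans_cluster(traj, k=2, seed=0)
    assert np.allclose(res.membership.iloc[-1], [0.5, 0.5], atol=0.02)


def test_cmeans_determinism_and_validation():
    rng = np.random.default_rng(5)
    traj = pd.DataFrame(rng.normal(size=(50, 5)))
    r1 = cmeans_cluster(traj, k=3, seed=7)
    r2 = cmeans_cluster(traj, k=3, seed=7)
    assert np.array_equal(r1.membership.values, r2.membership.values)
    with pytest.raises(ValueError):
        cmeans_cluster(traj, k=1)
    with pytest.raises(ValueError):
        cmeans_cluster(traj.iloc[:2], k=3)


# ---------------------------------------------------------------------------
# archetype assignment
# ---------------------------------------------------------------------------


def _result_with_centroids(centroids):
    k = len(centroids)
    idx = [f"p{i}" for i in range(k)]
    memb = pd.DataFrame(np.eye(k), index=idx, columns=range(1, k + 1))
    from enhdyn.dynamics import CmeansResult

    return CmeansResult(
        membership=memb,
        centroids=pd.DataFrame(np.asarray(centroids), index=range(1, k + 1)),
        hard_cluster=pd.Series(range(1, k + 1), index=idx),
        membership_score=pd.Series(1.0, index=idx),
    )


def test_assign_groups_identity_and_negation():
    z = lambda v: (np.asarray(v) - np.mean(v)) / np.std(v)
    primed = z(DEFAULT_ARCHETYPES["PE^PRIMED"])
    pe_on = z(DEFAULT_ARCHETYPES["PE^ON"])
    res = assign_groups(_result_with_centroids([primed, -pe_on]))
    assert res.cluster_to_group[1] == "PE^PRIMED"
    assert res.cluster_to_group[2] != "PE^ON"


def test_assign_groups_merges_similar_centroids():
    z = lambda v: (np.asarray(v) - np.mean(v)) / np.std(v)
    tr = z(DEFAULT_ARCHETYPES["VFG^TR"])
    rng = np.random.default_rng(0)
    cents = [z(DEFAULT_ARCHETYPES[g]) for g in DEFAULT_ARCHETYPES] + [
        tr + rng.normal(0, 0.05, 5),
        tr + rng.normal(0, 0.05, 5),
    ]
    res = assign_groups(_result_with_centroids(cents))
    groups = list(res.cluster_to_group.values())
    assert groups.count("VFG^TR") == 3
    assert set(groups) == set(DEFAULT_ARCHETYPES)


# ---------------------------------------------------------------------------
# pairwise OPEN/CLOSE and cross-protocol classes
# ---------------------------------------------------------------------------


def test_pairwise_open_close_classes():
    rng = np.random.default_rng(0)
    stages = ["ESC", "ADE", "VFGp3", "VFGp6", "PE"]
    lo, hi = 10, 400

    def traj(pattern):
        return {
            st: (np.array([hi, hi]) if p else np.array([lo, lo])).tolist()
            for st, p in zip(stages, pattern)
        }

    counts = {
        "open3": traj([0, 0, 1, 1, 1]),
        "close3": traj([0, 1, 0, 0, 0]),
        "open6": traj([0, 0, 0, 1, 1]),
        "close6": traj([0, 1, 1, 0, 0]),
        "flat": traj([1, 1, 1, 1, 1]),
    }
    for i in range(30):  # background for BH adjustment
        v = int(rng.integers(20, 200))
        counts[f"bg{i}"] = {st: [v, v] for st in stages}
    m = make_matrix(counts, stage_order=stages)
    cls = pairwise_open_close(m)
    assert cls["open3"] == "VFGp3^OPEN"
    assert cls["close3"] == "VFGp3^CLOSE"
    assert cls["open6"] == "VFGp6^OPEN"
    assert cls["close6"] == "VFGp6^CLOSE"
    assert cls["flat"] == "none"
    # classes are mutually exclusive by construction: one label per peak
    assert cls.index.is_unique


def test_stage_pair_sign_convention():
    counts = {"up": {"A": [20, 20], "B": [300, 320]}, "dn": {"A": [300, 320], "B": [20, 20]}}
    counts.update({f"bg{i}": {"A": [50, 55], "B": [52, 48]} for i in range(10)})
    m = make_matrix(counts, stage_order=["A", "B"])
    t = stage_pair_test(m, "A", "B")
    assert t.loc["up", "log2fc"] > 2 and t.loc["dn", "log2fc"] < -2


def test_cross_protocol_set_algebra():
    own = {
        "PE^PRIMED": make_atlas([("chr1", 0, 100)], names=["a"]),
        "PE^ON": make_atlas([("chr1", 1000, 1100), ("chr1", 3000, 3100)], names=["b", "c"]),
        "VFG^OFF": make_atlas([("chr1", 5000, 5100)], names=["d"]),
        "VFG^TR": make_atlas([("chr1", 7000, 7100)], names=["e"]),
    }
    external = {
        "DE": make_atlas([("chr1", 5050, 5200)]),
        "PP1": make_atlas([("chr1", 1050, 1200), ("chr1", 7050, 7200)]),
    }
    out = cross_protocol_classes(own, external)
    trips = lambda k: [(iv.chrom, iv.start, iv.end) for iv in out[k]]
    assert trips("PE-PP1-common") == [("chr1", 1000, 1100)]
    assert trips("PE-not-PP1") == [("chr1", 0, 100), ("chr1", 3000, 3100)]
    assert trips("VFG^OFF-in-DE-PP1") == [("chr1", 5000, 5100)]
    assert trips("VFG^TR-in-PP1") == [("chr1", 7000, 7100)]
    # empty external: everything falls to the "not" class
    empty = {"DE": PeakAtlas([]), "PP1": PeakAtlas([])}
    out2 = cross_protocol_classes(own, empty)
    assert len(out2["PE-PP1-common"]) == 0 and len(out2["PE-not-PP1"]) == 3
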