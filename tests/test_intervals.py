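"""Interval algebra against brute-force all-pairs oracles, plus BED I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhdyn.intervals import (
    GenomicInterval,
    InsertionEvent,
    PeakAtlas,
    consensus_atlas,
    insertion_coverage,
    intersect,
    merge_intervals,
    read_bed,
    reproducible_peaks,
    tn5_shift,
    tn5_shift_all,
    write_bed,
)

from conftest import make_atlas, random_intervals


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_intersect(a_trips, b_trips, frac, reciprocal, mode):
    """All-pairs scan with exact integer arithmetic (independent of the
    sweep implementation)."""
    from fractions import Fraction

    fr = Fraction(frac)
    num, den = fr.numerator, fr.denominator
    out = []
    for ac, as_, ae in a_trips:
        any_overlap = False
        passes = False
        for bc, bs, be in b_trips:
            if ac != bc:
                continue
            ov = min(ae, be) - max(as_, bs)
            if ov <= 0:
                continue
            any_overlap = True
            ok = ov * den >= num * (ae - as_)
            if reciprocal:
                ok = ok and ov * den >= num * (be - bs)
            if ok:
                passes = True
        if mode == "report_a" and passes:
            out.append((ac, as_, ae))
        if mode == "unique_a" and not any_overlap:
            out.append((ac, as_, ae))
    return sorted(out)


def brute_merge(trips, max_gap=0):
    """Pairwise union by repeated merging until fixpoint."""
    items = sorted(trips)
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                ci, si, ei = items[i]
                cj, sj, ej = items[j]
                if ci == cj and sj <= ei + max_gap and si <= ej + max_gap:
                    items[i] = (ci, min(si, sj), max(ei, ej))
                    items.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(items)


def atlas_triples(atlas):
    return sorted((iv.chrom, iv.start, iv.end) for iv in atlas)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------


def test_read_bed_three_columns_autonames(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\n")
    atlas = read_bed(p)
    iv = atlas[0]
    assert (iv.chrom, iv.start, iv.end, iv.name) == ("chr1", 100, 200, "peak000001")


def test_read_bed_empty_file(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("")
    assert len(read_bed(p)) == 0


def test_read_bed_sorts_like_independent_sort(tmp_path):
    rng = np.random.default_rng(1)
    trips = random_intervals(rng, 80)
    p = tmp_path / "a.bed"
    p.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in trips))
    atlas = read_bed(p)
    assert [(iv.chrom, iv.start, iv.end) for iv in atlas] == sorted(trips)
    # names follow genomic order
    assert [iv.name for iv in atlas] == [f"peak{i + 1:06d}" for i in range(len(trips))]


@pytest.mark.parametrize(
    "line,msg",
    [("chr1\t100\n", "line 1"), ("chr1\t200\t100\n", "line 1"), ("chr1\tx\t200\n", "line 1")],
)
def test_read_bed_malformed_line_names_line_number(tmp_path, line, msg):
    p = tmp_path / "bad.bed"
    p.write_text(line)
    with pytest.raises(ValueError, match=msg):
        read_bed(p)


def test_bed_roundtrip_gzip(tmp_path):
    atlas = make_atlas([("chr1", 5, 50), ("chr2", 0, 10)], names=["a", "b"])
    p = tmp_path / "x.bed.gz"
    write_bed(atlas, p)
    back = read_bed(p)
    assert atlas_triples(back) == atlas_triples(atlas)
    assert [iv.name for iv in back] == ["a", "b"]


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 5, 5)
    with pytest.raises(ValueError):
        PeakAtlas([GenomicInterval("chr1", 0, 5, "x"), GenomicInterval("chr1", 6, 9, "x")])


# ---------------------------------------------------------------------------
# merge / intersect / consensus vs oracles
# ---------------------------------------------------------------------------


def test_merge_simple_and_disjoint():
    assert atlas_triples(merge_intervals(make_atlas([("chr1", 0, 10), ("chr1", 5, 20)]))) == [
        ("chr1", 0, 20)
    ]
    disjoint = [("chr1", 0, 10), ("chr1", 20, 30), ("chr2", 0, 5)]
    assert atlas_triples(merge_intervals(make_atlas(disjoint))) == sorted(disjoint)


def test_merge_matches_bruteforce_union():
    rng = np.random.default_rng(7)
    trips = random_intervals(rng, 500, span=5_000)
    assert atlas_triples(merge_intervals(make_atlas(trips))) == brute_merge(trips)


def test_reciprocal_boundary_fraction_is_inclusive():
    a = make_atlas([("chr1", 100, 200)])
    b = make_atlas([("chr1", 150, 250)])
    hit = intersect(a, b, min_frac_a=0.5, reciprocal=True)
    assert atlas_triples(hit) == [("chr1", 100, 200)]


def test_unique_a_different_chromosome():
    a = make_atlas([("chr1", 100, 200)])
    b = make_atlas([("chr2", 100, 200)])
    assert atlas_triples(intersect(a, b, mode="unique_a")) == [("chr1", 100, 200)]


def test_intersect_rejects_bad_fraction():
    a = make_atlas([("chr1", 0, 10)])
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            intersect(a, a, min_frac_a=bad)


@pytest.mark.parametrize("frac", [0.25, 0.5, 0.75, 1.0, 0.3])
@pytest.mark.parametrize("reciprocal", [False, True])
@pytest.mark.parametrize("mode", ["report_a", "unique_a"])
def test_intersect_matches_allpairs_oracle(frac, reciprocal, mode):
    rng = np.random.default_rng(int(frac * 100) + reciprocal)
    a_trips = random_intervals(rng, 300, span=6_000)
    b_trips = random_intervals(rng, 300, span=6_000)
    got = atlas_triples(intersect(make_atlas(a_trips), make_atlas(b_trips), frac, reciprocal, mode))
    assert got == brute_intersect(a_trips, b_trips, frac, reciprocal, mode)


def test_reproducible_peaks_identity_disjoint_and_oracle():
    rng = np.random.default_rng(3)
    trips = random_intervals(rng, 100)
    atlas = make_atlas(trips)
    assert atlas_triples(reproducible_peaks(atlas, atlas)) == atlas_triples(atlas)
    far = make_atlas([("chr9", 0, 10)])
    assert len(reproducible_peaks(atlas, far)) == 0
    other = make_atlas(random_intervals(rng, 100))
    assert atlas_triples(reproducible_peaks(atlas, other)) == brute_intersect(
        sorted(trips), atlas_triples(other), 0.5, True, "report_a"
    )


def test_consensus_union_of_covered_bases():
    rng = np.random.default_rng(11)
    stage_sets = [random_intervals(rng, 120, span=4_000) for _ in range(5)]
    cons = consensus_atlas([make_atlas(t) for t in stage_sets])
    all_trips = [t for ts in stage_sets for t in ts]
    assert atlas_triples(cons) == brute_merge(all_trips)
    # fresh sequential names
    assert [iv.name for iv in cons] == [f"peak{i + 1:06d}" for i in range(len(cons))]


def test_consensus_single_atlas_renames_only():
    atlas = make_atlas([("chr1", 0, 10), ("chr1", 50, 60)], names=["x", "y"])
    cons = consensus_atlas([atlas])
    assert atlas_triples(cons) == atlas_triples(atlas)
    assert [iv.name for iv in cons] == ["peak000001", "peak000002"]


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 60)).map(
            lambda t: ("chr1", t[0], t[0] + t[1])
        ),
        min_size=1,
        max_size=40,
    )
)
def test_merge_idempotent_and_coverage_preserving(trips):
    atlas = make_atlas(trips)
    merged = merge_intervals(atlas)
    assert atlas_triples(merge_intervals(merged)) == atlas_triples(merged)
    assert merged.covered_bases() == atlas.covered_bases()
    # merged output is pairwise disjoint and sorted
    prev = None
    for iv in merged:
        if prev is not None and prev.chrom == iv.chrom:
            assert iv.start > prev.end - 1 and iv.start >= prev.start
        prev = iv


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    st.lists(
        st.tuples(st.integers(0, 300), st.integers(1, 40)).map(
            lambda t: ("chr1", t[0], t[0] + t[1])
        ),
        min_size=1,
        max_size=25,
        unique=True,
    ),
    st.sampled_from([0.1, 0.5, 1.0]),
)
def test_self_intersect_identity(trips, frac):
    atlas = make_atlas(trips)
    assert atlas_triples(intersect(atlas, atlas, frac, True)) == atlas_triples(atlas)


# ---------------------------------------------------------------------------
# Tn5 shift and insertion coverage
# ---------------------------------------------------------------------------


def test_tn5_shift_offsets():
    assert tn5_shift(InsertionEvent("chr1", 1000, "+")).position == 1004
    assert tn5_shift(InsertionEvent("chr1", 2000, "-")).position == 1995


def test_tn5_shift_clips_at_zero_with_warning():
    with pytest.warns(UserWarning, match="clipped"):
        ev = tn5_shift(InsertionEvent("chr1", 2, "-"))
    assert ev.position == 0
    with pytest.raises(ValueError):
        tn5_shift(InsertionEvent("chr1", 5, "?"))
    shifted, n_clipped = tn5_shift_all(
        [InsertionEvent("chr1", 2, "-"), InsertionEvent("chr1", 50, "+")]
    )
    assert n_clipped == 1 and [e.position for e in shifted] == [0, 54]


def test_insertion_coverage_single_and_stacked():
    assert insertion_coverage([InsertionEvent("chr1", 100)], 30) == [("chr1", 85, 115, 1)]
    two = insertion_coverage([InsertionEvent("chr1", 100)] * 2, 30)
    assert two == [("chr1", 85, 115, 2)]
    with pytest.raises(ValueError):
        insertion_coverage([], width=31)


def test_insertion_coverage_matches_dense_oracle():
    rng = np.random.default_rng(5)
    events = [
        InsertionEvent("chr1", int(rng.integers(0, 2_000))) for _ in range(1_000)
    ]
    width = 30
    dense = np.zeros(2_200, dtype=int)
    clipped = 0
    for ev in events:
        s = ev.position - width // 2
        clipped += max(0, -s)
        dense[max(0, s) : ev.position + width // 2] += 1
    rec = insertion_coverage(events, width)
    rebuilt = np.zeros_like(dense)
    for chrom, s, e, d in rec:
        assert chrom == "chr1" and e > s and d > 0
        rebuilt[s:e] = d
    assert np.array_equal(rebuilt, dense)
    # total mass = width x events, less the bases clipped at the contig edge
    assert sum((e - s) * d for _, s, e, d in rec) == width * len(events) - clipped
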