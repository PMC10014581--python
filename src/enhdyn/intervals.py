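"""Genomic interval algebra and BED/bedGraph plumbing.

All coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Chromosome names are compared by exact string match —
``chr1`` and ``1`` are different sequences on purpose, so that mismatched
inputs fail loudly instead of silently producing empty overlaps.

The overlap-fraction test is carried out in exact rational arithmetic
(``fractions.Fraction``) so that boundary cases such as a 50 bp overlap of a
100 bp interval at ``min_frac=0.5`` are decided without float ties.
"""

from __future__ import annotations

import gzip
import warnings
from bisect import bisect_right
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakAtlas",
    "InsertionEvent",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_insertions_tsv",
    "merge_intervals",
    "intersect",
    "intersect_any",
    "tn5_shift",
    "tn5_shift_all",
    "insertion_coverage",
    "reproducible_peaks",
    "consensus_atlas",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class InsertionEvent:
    """A single transposase insertion site (0-based bp)."""

    chrom: str
    position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")


class PeakAtlas:
    """An ordered, uniquely named collection of genomic intervals.

    The atlas is the universe against which every downstream classification
    is defined.  Intervals are always kept sorted by ``(chrom, start, end)``
    and names, when present, must be unique.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        genome_label: str = "",
        *,
        presorted: bool = False,
    ) -> None:
        ivs = list(intervals)
        if not presorted:
            ivs.sort(key=GenomicInterval.sort_key)
        self.intervals: list[GenomicInterval] = ivs
        self.genome_label = genome_label
        names = [iv.name for iv in ivs if iv.name is not None]
        if len(names) != len(set(names)):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate interval name: {dup!r}")
        self.id_index: dict[str, GenomicInterval] = {
            iv.name: iv for iv in ivs if iv.name is not None
        }
        # per-chromosome coordinate arrays for vectorised overlap queries
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        chroms: dict[str, list[int]] = {}
        for i, iv in enumerate(ivs):
            chroms.setdefault(iv.chrom, []).append(i)
        for chrom, idx in chroms.items():
            idx_a = np.asarray(idx, dtype=np.int64)
            self._by_chrom[chrom] = (
                np.asarray([ivs[i].start for i in idx], dtype=np.int64),
                np.asarray([ivs[i].end for i in idx], dtype=np.int64),
                idx_a,
            )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakAtlas):
            return NotImplemented
        return [
            (iv.chrom, iv.start, iv.end) for iv in self.intervals
        ] == [(iv.chrom, iv.start, iv.end) for iv in other.intervals]

    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def with_names(self, prefix: str = "peak") -> "PeakAtlas":
        """Return a copy with fresh sequential names ``peak000001`` ... in sorted order."""
        renamed = [
            GenomicInterval(iv.chrom, iv.start, iv.end, f"{prefix}{i + 1:06d}", iv.score)
            for i, iv in enumerate(self.intervals)
        ]
        return PeakAtlas(renamed, self.genome_label, presorted=True)

    def covered_bases(self) -> int:
        total = 0
        for atlas_chrom in self._by_chrom:
            starts, ends, _ = self._by_chrom[atlas_chrom]
            order = np.argsort(starts, kind="stable")
            cur_s, cur_e = None, None
            for s, e in zip(starts[order], ends[order]):
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = int(s), int(e)
                else:
                    cur_e = max(cur_e, int(e))
            if cur_e is not None:
                total += cur_e - cur_s
        return total


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path: str | Path, genome_label: str = "") -> PeakAtlas:
    """Read BED3/BED4/BED6 into a :class:`PeakAtlas`.

    Rows are sorted by ``(chrom, start, end)``.  If the name column is
    absent, sequential names ``peak000001`` ... are assigned *after*
    sorting so that names follow genomic order.
    """
    raw: list[tuple[str, int, int, str | None, float | None]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if end <= start or start < 0:
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else None
            score: float | None = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                score = float(fields[4])
            raw.append((chrom, start, end, name, score))

    raw.sort(key=lambda r: (r[0], r[1], r[2]))
    have_names = any(r[3] is not None for r in raw)
    ivs = []
    for i, (chrom, start, end, name, score) in enumerate(raw):
        if not have_names:
            name = f"peak{i + 1:06d}"
        ivs.append(GenomicInterval(chrom, start, end, name, score))
    return PeakAtlas(ivs, genome_label, presorted=True)


def write_bed(atlas: PeakAtlas, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in atlas:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(f"{iv.score:g}")
            fh.write("\t".join(cols) + "\n")


def write_bedgraph(
    records: Iterable[tuple[str, int, int, int]], path: str | Path
) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, start, end, depth in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


def read_insertions_tsv(path: str | Path) -> list[InsertionEvent]:
    """Read insertion events from a TSV of (chrom, position, strand)."""
    events = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            events.append(InsertionEvent(fields[0], int(fields[1]), fields[2]))
    return events


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(atlas: PeakAtlas, max_gap: int = 0) -> PeakAtlas:
    """Merge book-ended/overlapping intervals (union of covered bases).

    Intervals closer than or equal to ``max_gap`` bp are merged.  Output is
    sorted, pairwise non-overlapping, with fresh sequential names.
    """
    merged: list[GenomicInterval] = []
    cur: list | None = None
    for iv in atlas:  # atlas is sorted
        if cur is not None and iv.chrom == cur[0] and iv.start <= cur[2] + max_gap:
            cur[2] = max(cur[2], iv.end)
        else:
            if cur is not None:
                merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
            cur = [iv.chrom, iv.start, iv.end]
    if cur is not None:
        merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
    return PeakAtlas(merged, atlas.genome_label, presorted=True).with_names()


def _overlap_passes(
    ov: int, len_a: int, len_b: int, frac: Fraction, reciprocal: bool
) -> bool:
    # exact integer comparison: ov/len >= frac  <=>  ov * den >= num * len
    if ov * frac.denominator < frac.numerator * len_a:
        return False
    if reciprocal and ov * frac.denominator < frac.numerator * len_b:
        return False
    return True


def intersect(
    a: PeakAtlas,
    b: PeakAtlas,
    min_frac_a: float = 1e-9,
    reciprocal: bool = False,
    mode: str = "report_a",
) -> PeakAtlas:
    """bedtools-style intersection of two atlases.

    ``mode="report_a"`` returns each *a* interval at most once if at least
    one *b* interval overlaps it by ``>= min_frac_a * len(a)`` bp (and, when
    ``reciprocal``, also ``>= min_frac_a * len(b)``) — the ``-f F [-r] -u``
    semantics.  ``mode="unique_a"`` returns *a* intervals with no overlap of
    any extent in *b* (the ``-v`` semantics; the fraction is ignored).
    """
    if mode not in ("report_a", "unique_a"):
        raise ValueError(f"unknown mode {mode!r}")
    if not (0 < min_frac_a <= 1):
        raise ValueError(f"min_frac_a must be in (0, 1], got {min_frac_a}")
    frac = Fraction(min_frac_a)

    hits: list[GenomicInterval] = []
    for chrom, (a_starts, a_ends, a_idx) in a._by_chrom.items():
        if chrom not in b._by_chrom:
            if mode == "unique_a":
                hits.extend(a.intervals[i] for i in a_idx)
            continue
        b_starts, b_ends, _ = b._by_chrom[chrom]
        order = np.argsort(b_starts, kind="stable")
        bs, be = b_starts[order], b_ends[order]
        bs_list = bs.tolist()
        for s, e, i in zip(a_starts.tolist(), a_ends.tolist(), a_idx.tolist()):
            hi = bisect_right(bs_list, e - 1)
            if hi == 0:
                if mode == "unique_a":
                    hits.append(a.intervals[i])
                continue
            cand_e = be[:hi]
            cand_s = bs[:hi]
            ovmask = cand_e > s
            if mode == "unique_a":
                if not ovmask.any():
                    hits.append(a.intervals[i])
                continue
            if not ovmask.any():
                continue
            ov = np.minimum(cand_e[ovmask], e) - np.maximum(cand_s[ovmask], s)
            lens_b = (cand_e[ovmask] - cand_s[ovmask]).tolist()
            len_a = e - s
            if any(
                _overlap_passes(int(o), len_a, int(lb), frac, reciprocal)
                for o, lb in zip(ov.tolist(), lens_b)
            ):
                hits.append(a.intervals[i])
    return PeakAtlas(hits, a.genome_label)


def intersect_any(a: PeakAtlas, b: PeakAtlas) -> PeakAtlas:
    """Report *a* intervals with >=1 bp overlap in *b* (``-u`` with no fraction)."""
    return intersect(a, b, min_frac_a=Fraction(1, 10**9), reciprocal=False)


def overlap_count(a: PeakAtlas, b: PeakAtlas) -> int:
    """Number of *a* intervals with any overlap in *b*."""
    return len(intersect_any(a, b))


def tn5_shift(event: InsertionEvent) -> InsertionEvent:
    """Shift a raw read 5' position to the Tn5 insertion site.

    Watson-strand reads move +4 bp, Crick-strand reads −5 bp.  Positions
    that would become negative are clipped to 0 with a warning.
    """
    if event.strand in ("+",):
        pos = event.position + 4
    elif event.strand in ("-", "−"):
        pos = event.position - 5
    else:
        raise ValueError(f"unknown strand symbol {event.strand!r}")
    if pos < 0:
        warnings.warn(
            f"Tn5 shift clipped negative position {pos} to 0 on {event.chrom}",
            stacklevel=2,
        )
        pos = 0
    return InsertionEvent(event.chrom, pos, event.strand)


def tn5_shift_all(events: Iterable[InsertionEvent]) -> tuple[list[InsertionEvent], int]:
    """Shift many events; returns (shifted events, number clipped at 0)."""
    out, n_clipped = [], 0
    for ev in events:
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out.append(tn5_shift(ev))
            n_clipped += sum(1 for _ in rec)
    return out, n_clipped


def insertion_coverage(
    events: Sequence[InsertionEvent], width: int = 30
) -> list[tuple[str, int, int, int]]:
    """Run-length-encoded per-base coverage of ``width`` bp windows centred
    on each insertion site.

    Each event contributes depth 1 to ``[pos - width/2, pos + width/2)``
    (clipped at 0).  Returns sorted, non-overlapping bedGraph records
    ``(chrom, start, end, depth)``; zero-depth runs are omitted.
    """
    if width <= 0 or width % 2:
        raise ValueError(f"width must be even and > 0, got {width}")
    half = width // 2
    deltas: dict[str, dict[int, int]] = {}
    for ev in events:
        d = deltas.setdefault(ev.chrom, {})
        s = max(0, ev.position - half)
        e = ev.position + half
        d[s] = d.get(s, 0) + 1
        d[e] = d.get(e, 0) - 1
    records: list[tuple[str, int, int, int]] = []
    for chrom in sorted(deltas):
        depth = 0
        prev_pos: int | None = None
        for pos in sorted(deltas[chrom]):
            if prev_pos is not None and depth > 0 and pos > prev_pos:
                records.append((chrom, prev_pos, pos, depth))
            depth += deltas[chrom][pos]
            prev_pos = pos
    return records


def reproducible_peaks(
    rep1: PeakAtlas,
    rep2: PeakAtlas,
    min_frac: float = 0.5,
    reciprocal: bool = True,
) -> PeakAtlas:
    """Replicate-consistent peaks: rep1 intervals passing the reciprocal
    fraction test against rep2 (``-f 0.50 -r -u`` semantics)."""
    return intersect(rep1, rep2, min_frac_a=min_frac, reciprocal=reciprocal)


def union_atlas(atlases: Sequence[PeakAtlas], genome_label: str = "") -> PeakAtlas:
    """Concatenate, sort and merge several atlases (fresh names)."""
    all_ivs = [
        GenomicInterval(iv.chrom, iv.start, iv.end) for at in atlases for iv in at
    ]
    label = genome_label or (atlases[0].genome_label if atlases else "")
    return merge_intervals(PeakAtlas(all_ivs, label))


def consensus_atlas(per_stage_reproducible: Sequence[PeakAtlas]) -> PeakAtlas:
    """Consensus peak set across stages: concatenate -> sort -> merge, then
    assign fresh sequential peak names."""
    if not per_stage_reproducible:
        raise ValueError("need at least one atlas")
    return union_atlas(per_stage_reproducible)
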