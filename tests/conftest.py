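import numpy as np
import pandas as pd
import pytest

from enhdyn.dynamics import AccessibilityMatrix
from enhdyn.intervals import GenomicInterval, PeakAtlas
from enhdyn.simulate import SimulationConfig, simulate_atac_timecourse


def make_atlas(triples, names=None):
    ivs = [
        GenomicInterval(c, s, e, names[i] if names else None)
        for i, (c, s, e) in enumerate(triples)
    ]
    return PeakAtlas(ivs)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=300):
    out = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, span))
        out.append((c, s, s + int(rng.integers(1, max_len))))
    return out


def make_matrix(stage_counts, stage_order=None, length=500, libsize=1e7):
    """Build an AccessibilityMatrix from {peak: {stage: [rep counts]}}."""
    peaks = list(stage_counts)
    stages = stage_order or list(next(iter(stage_counts.values())))
    cols, data = [], {p: [] for p in peaks}
    for stage in stages:
        n_rep = len(next(iter(stage_counts.values()))[stage])
        for r in range(n_rep):
            cols.append(f"{stage}_rep{r + 1}")
            for p in peaks:
                data[p].append(stage_counts[p][stage][r])
    counts = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    samples = pd.DataFrame(
        {
            "stage": [c.rsplit("_rep", 1)[0] for c in cols],
            "replicate": [int(c.rsplit("_rep", 1)[1]) for c in cols],
            "library_size": [libsize] * len(cols),
        },
        index=pd.Index(cols, name="sample"),
    )
    atlas = PeakAtlas(
        [
            GenomicInterval("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + length, p)
            for i, p in enumerate(peaks)
        ]
    )
    return AccessibilityMatrix(counts, atlas, samples, tuple(stages))


@pytest.fixture(scope="session")
def small_sim():
    """A reduced synthetic time course shared across module tests."""
    cfg = SimulationConfig(
        seed=202,
        n_peaks_per_group=60,
        n_static_peaks=240,
        n_noise_genes=60,
        tissue_private_regions=60,
    )
    return simulate_atac_timecourse(cfg)
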