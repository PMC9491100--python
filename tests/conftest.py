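import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from urodmas import (
    CaptureRegion,
    CytosineRecord,
    DMASMatrix,
    build_windows,
    mine_patterns,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def tiny_catalog():
    """Two regions, 2 + 3 retained windows of 10 bp."""
    regions = [
        CaptureRegion("chr1", 0, 25, "rA"),  # windows [0,10), [10,20); 5 bp dropped
        CaptureRegion("chr2", 100, 130, "rB"),  # [100,110), [110,120), [120,130)
    ]
    return build_windows(regions, window_length=10)


@pytest.fixture
def separating_fixture(tiny_catalog):
    """Six samples whose orderings on rB windows separate perfectly.

    Healthy samples order rB windows 3 < 1 < 2; cancer samples 2 < 1 < 3.
    The rA columns are identical across everyone (no contrast there).
    """
    sample_ids = [f"h{i}" for i in range(3)] + [f"c{i}" for i in range(3)]
    window_ids = tiny_catalog.window_ids  # rA.0 rA.1 rB.0 rB.1 rB.2
    rows = []
    for i in range(3):  # healthy: rB DMAS (0.5, 0.9, 0.1) -> order 2,0,1
        rows.append([0.3, 0.3, 0.5 + 0.01 * i, 0.9, 0.1])
    for i in range(3):  # cancer: rB DMAS (0.5, 0.1, 0.9) -> order 1,0,2
        rows.append([0.3, 0.3, 0.5 + 0.01 * i, 0.1, 0.9])
    dmas = DMASMatrix(sample_ids, window_ids, np.array(rows))
    labels = {s: ("healthy" if s.startswith("h") else "cancer") for s in sample_ids}
    return dmas, labels


@pytest.fixture
def separating_model(separating_fixture, tiny_catalog):
    dmas, labels = separating_fixture
    return mine_patterns(dmas, labels, tiny_catalog, k=3, delta_min=0.5)


def naive_aggregate(catalog, records):
    """Per-site loop oracle for window aggregation (one sample)."""
    methyl = np.zeros(len(catalog), dtype=np.int64)
    unmethyl = np.zeros(len(catalog), dtype=np.int64)
    for rec in records:
        for i, w in enumerate(catalog.windows):
            if rec.chrom == w.chrom and w.start < rec.pos <= w.end:
                methyl[i] += rec.n_meth
                unmethyl[i] += rec.n_unmeth
                break
    return methyl, unmethyl


def random_panel_and_sites(rng, max_regions=10):
    """A random small panel and scattered cytosine records for oracle tests."""
    n_regions = rng.integers(1, max_regions + 1)
    regions = []
    cursor = {c: int(rng.integers(0, 50)) for c in ("chr1", "chr2")}
    for i in range(n_regions):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        start = cursor[chrom]
        length = int(rng.integers(1, 2001))
        regions.append(CaptureRegion(chrom, start, start + length, f"r{i}"))
        cursor[chrom] = start + length + int(rng.integers(1, 100))
    records = []
    n_sites = int(rng.integers(0, 200))
    hi = max(cursor.values()) + 100
    for _ in range(n_sites):
        records.append(
            CytosineRecord(
                chrom="chr1" if rng.random() < 0.5 else "chr2",
                pos=int(rng.integers(1, hi)),
                strand="+" if rng.random() < 0.5 else "-",
                n_meth=int(rng.integers(0, 20)),
                n_unmeth=int(rng.integers(0, 20)),
                context=("CpG", "CHG", "CHH")[rng.integers(0, 3)],
            )
        )
    return regions, records
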