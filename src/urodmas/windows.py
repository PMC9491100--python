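"""Fixed-length windowing of capture regions and per-window count aggregation.

Each capture region of length L is tiled with floor(L / window_length)
non-overlapping windows anchored at the region start; the sub-window
remainder at the 3' end of the region is dropped.  Per-cytosine counts are
then summed into windows: a 1-based report position p belongs to the
0-based half-open window [s, e) iff s < p <= e.  Windows never covered by
any site still appear in the matrix with counts (0, 0).
"""

from __future__ import annotations

import logging
from itertools import islice
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .types import (
    CaptureRegion,
    CountMatrix,
    CytosineRecord,
    ValidationError,
    Window,
    WindowCatalog,
)

logger = logging.getLogger(__name__)

_CHUNK = 200_000


def build_windows(regions: Iterable[CaptureRegion], window_length: int = 500) -> WindowCatalog:
    """Tile every region with fixed-length windows; drop short remainders.

    A region shorter than ``window_length`` contributes no windows.
    Window ids are ``<region_id>.<ordinal>`` with a zero-based ordinal.
    """
    if window_length < 1:
        raise ValidationError(f"window_length must be >= 1, got {window_length}")
    windows: list[Window] = []
    regions = sorted(regions, key=lambda r: (r.chrom, r.start))
    n_dropped_regions = 0
    for region in regions:
        n_win = region.length // window_length
        if n_win == 0:
            n_dropped_regions += 1
            continue
        for i in range(n_win):
            start = region.start + i * window_length
            windows.append(
                Window(
                    window_id=f"{region.region_id}.{i}",
                    region_id=region.region_id,
                    chrom=region.chrom,
                    start=start,
                    end=start + window_length,
                    index_in_region=i,
                )
            )
    if n_dropped_regions:
        logger.info(
            "%d regions shorter than %d bp yielded no windows", n_dropped_regions, window_length
        )
    return WindowCatalog(windows, window_length)


class _WindowIndex:
    """searchsorted-based locator from (chrom, 1-based pos) to catalog column."""

    def __init__(self, catalog: WindowCatalog):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for col, w in enumerate(catalog.windows):
            per_chrom.setdefault(w.chrom, []).append((w.start, w.end, col))
        for chrom, triples in per_chrom.items():
            triples.sort()
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            cols = np.array([t[2] for t in triples], dtype=np.int64)
            self.by_chrom[chrom] = (starts, ends, cols)

    def locate(self, chrom: str, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (valid mask, catalog column) for 1-based positions on chrom."""
        if chrom not in self.by_chrom:
            return np.zeros(len(pos), dtype=bool), np.zeros(len(pos), dtype=np.int64)
        starts, ends, cols = self.by_chrom[chrom]
        q = np.asarray(pos, dtype=np.int64) - 1  # 0-based site coordinate
        idx = np.searchsorted(starts, q, side="right") - 1
        valid = (idx >= 0) & (q < ends[np.clip(idx, 0, len(ends) - 1)])
        return valid, cols[np.clip(idx, 0, len(cols) - 1)]


Report = Union[pd.DataFrame, Iterable[CytosineRecord]]


def _records_to_chunks(report: Report) -> Iterable[pd.DataFrame]:
    if isinstance(report, pd.DataFrame):
        yield report
        return
    it = iter(report)
    while True:
        chunk = list(islice(it, _CHUNK))
        if not chunk:
            return
        yield pd.DataFrame(chunk, columns=list(CytosineRecord._fields))


def aggregate_counts(catalog: WindowCatalog, reports: Mapping[str, Report]) -> CountMatrix:
    """Sum per-cytosine counts into catalog windows for each sample.

    ``reports`` maps sample id to either a stream of :class:`CytosineRecord`
    or a DataFrame with columns chrom/pos/n_meth/n_unmeth (both strands and
    all retained contexts contribute).  Sites outside every retained window
    are dropped; the dropped-site tally is logged.
    """
    if len(catalog) == 0:
        raise ValidationError("cannot aggregate into an empty window catalog")
    index = _WindowIndex(catalog)
    sample_ids = list(reports.keys())
    n_s, n_w = len(sample_ids), len(catalog)
    methyl = np.zeros((n_s, n_w), dtype=np.int64)
    unmethyl = np.zeros((n_s, n_w), dtype=np.int64)
    n_dropped = 0
    for row, sid in enumerate(sample_ids):
        report = reports[sid]
        if report is None:
            raise ValidationError(f"no cytosine report available for sample {sid!r}")
        for chunk in _records_to_chunks(report):
            for chrom, sub in chunk.groupby("chrom", sort=False):
                valid, cols = index.locate(chrom, sub["pos"].to_numpy())
                n_dropped += int((~valid).sum())
                np.add.at(methyl[row], cols[valid], sub["n_meth"].to_numpy()[valid])
                np.add.at(unmethyl[row], cols[valid], sub["n_unmeth"].to_numpy()[valid])
    if n_dropped:
        logger.info("%d sites fell outside all retained windows and were dropped", n_dropped)
    return CountMatrix(sample_ids, catalog.window_ids, methyl, unmethyl)
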