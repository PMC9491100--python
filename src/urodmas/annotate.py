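"""Nearest-gene assignment for pattern windows.

A window overlapping one or more genes maps to the gene with the largest
overlap (ties: smaller gene start).  An intergenic window maps to the gene
with the smallest boundary distance, 0 when intervals touch (ties: the
lower-coordinate, i.e. upstream, gene).  Strand is ignored for distance.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .types import GeneRecord, Window

logger = logging.getLogger(__name__)


def assign_genes(windows: Iterable[Window], genes: Sequence[GeneRecord]) -> dict[str, str]:
    """Map each window id to its assigned gene id.

    Windows on chromosomes without any gene are left out of the mapping
    (logged).  Assignment is deterministic.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gl in by_chrom.values():
        gl.sort(key=lambda g: (g.start, g.end))

    arrays = {
        chrom: (
            np.array([g.start for g in gl], dtype=np.int64),
            np.array([g.end for g in gl], dtype=np.int64),
        )
        for chrom, gl in by_chrom.items()
    }

    out: dict[str, str] = {}
    n_unassigned = 0
    for w in windows:
        if w.chrom not in by_chrom:
            n_unassigned += 1
            continue
        starts, ends = arrays[w.chrom]
        overlap = np.minimum(ends, w.end) - np.maximum(starts, w.start)
        if overlap.max() > 0:
            best = np.flatnonzero(overlap == overlap.max())
            # ties resolved toward the smaller gene start; genes are start-sorted
            out[w.window_id] = by_chrom[w.chrom][best[0]].gene_id
        else:
            # boundary distance between closed intervals; 0 when touching
            dist = np.maximum(np.maximum(starts - w.end, w.start - ends), 0)
            best = np.flatnonzero(dist == dist.min())
            out[w.window_id] = by_chrom[w.chrom][best[0]].gene_id
    if n_unassigned:
        logger.warning("%d windows lie on chromosomes with no annotated gene", n_unassigned)
    return out
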