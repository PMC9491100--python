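"""Rank-ordering-pattern classifier over DMAS profiles.

The classifier looks at tuples of k consecutive retained windows within a
capture region and records, per sample, the relative order of their DMAS
values (a permutation).  A (tuple, permutation) pair observed frequently in
one class and rarely in the other is a class-specific pattern; its weight
is the frequency contrast.  A sample's H-score (C-score) is the summed
weight of healthy-specific (cancer-specific) patterns it matches; D = H - C,
and the final z score standardizes D within the batch of samples scored
together.  Low z means high cancer risk.

Mining is exhaustive over all sliding tuples and all k! permutations, with
deterministic tie-breaking everywhere, so identical inputs give
byte-identical serialized models.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    DMASMatrix,
    OrderingPattern,
    PatternModel,
    TupleFeature,
    ValidationError,
    WindowCatalog,
)

logger = logging.getLogger(__name__)

CLASS_LABELS = ("healthy", "cancer")


def observed_ordering(dmas_values: Sequence[float], window_indices: Sequence[int] | None = None) -> tuple[int, ...]:
    """The permutation sorting DMAS values ascending, ties by genomic order.

    Returns local offsets (0..k-1) in ascending-DMAS order; e.g. values
    (0.5, 0.9, 0.1) give (2, 0, 1): window 3 < window 1 < window 2.  A
    stable sort realizes the tie rule (earlier window ranks first), so the
    result is total and deterministic — zero-coverage ties included.
    """
    values = np.asarray(dmas_values, dtype=float)
    if window_indices is not None:
        order = np.argsort(np.asarray(window_indices))
        if not np.array_equal(order, np.arange(len(values))):
            raise ValidationError("window_indices must be increasing")
    return tuple(int(i) for i in np.argsort(values, kind="stable"))


def tuple_features(catalog: WindowCatalog, k: int) -> list[TupleFeature]:
    """All sliding (stride-1) tuples of k consecutive windows per region."""
    feats: list[TupleFeature] = []
    for region_id, cols in catalog.regions().items():
        wins = [catalog.windows[c] for c in cols]
        for i in range(len(wins) - k + 1):
            feats.append(
                TupleFeature(
                    region_id=region_id,
                    window_ids=tuple(w.window_id for w in wins[i : i + k]),
                    start_index=wins[i].index_in_region,
                )
            )
    return feats


def _feature_columns(features: Sequence[TupleFeature], window_ids: Sequence[str]) -> np.ndarray:
    index = {w: i for i, w in enumerate(window_ids)}
    missing = sorted(
        {w for f in features for w in f.window_ids if w not in index}
    )
    if missing:
        raise ValidationError(f"windows referenced but absent from DMAS matrix: {missing[:10]}")
    return np.array([[index[w] for w in f.window_ids] for f in features], dtype=np.int64)


def _ordering_codes(values: np.ndarray, cols: np.ndarray, k: int) -> np.ndarray:
    """Encode the observed ordering of each (sample, tuple) as one integer.

    Code = sum(perm[r] * k**r) over rank positions r; stable argsort makes
    ties resolve to genomic order.
    """
    tuples = values[:, cols]  # samples x tuples x k
    perm = np.argsort(tuples, axis=2, kind="stable")
    base = k ** np.arange(k, dtype=np.int64)
    return perm @ base


def _decode(code: int, k: int) -> tuple[int, ...]:
    out = []
    for _ in range(k):
        out.append(code % k)
        code //= k
    return tuple(out)


def mine_patterns(
    dmas: DMASMatrix,
    labels: Mapping[str, str],
    catalog: WindowCatalog,
    k: int = 3,
    delta_min: float = 0.5,
    max_patterns_per_class: int = 2000,
    metadata: Mapping | None = None,
) -> PatternModel:
    """Exhaustively mine class-specific ordering patterns.

    For every tuple feature and every permutation, the pattern frequency in
    each class is the fraction of that class's training samples showing the
    permutation.  Patterns with frequency contrast >= ``delta_min`` are
    kept for the majority class, weighted by the contrast, ranked by weight
    (ties by region id, start index, permutation code) and truncated to
    ``max_patterns_per_class``.
    """
    if not 2 <= k <= 4:
        raise ValidationError(f"k must be in 2..4, got {k}")
    if not 0 < delta_min <= 1:
        raise ValidationError(f"delta_min must be in (0, 1], got {delta_min}")
    unknown = set(labels.values()) - set(CLASS_LABELS)
    if unknown:
        raise ValidationError(f"labels must be 'healthy' or 'cancer', got {sorted(unknown)}")
    sample_class = [labels[s] for s in dmas.sample_ids if s in labels]
    if len(sample_class) != len(dmas.sample_ids):
        missing = [s for s in dmas.sample_ids if s not in labels]
        raise ValidationError(f"samples without labels: {missing[:10]}")
    mask_h = np.array([c == "healthy" for c in sample_class])
    mask_c = ~mask_h
    n_h, n_c = int(mask_h.sum()), int(mask_c.sum())
    if n_h == 0 or n_c == 0:
        raise ValidationError(f"need samples in both classes (healthy={n_h}, cancer={n_c})")

    features = tuple_features(catalog, k)
    model = PatternModel(
        k=k,
        delta_min=delta_min,
        max_patterns_per_class=max_patterns_per_class,
        metadata=dict(metadata or {}),
    )
    if not features:
        logger.warning("no region has >= %d windows; model is empty", k)
        return model

    cols = _feature_columns(features, dmas.window_ids)
    codes = _ordering_codes(dmas.values, cols, k)  # samples x tuples
    n_codes = k**k
    n_tuples = len(features)
    counts_h = np.zeros((n_tuples, n_codes), dtype=np.int64)
    counts_c = np.zeros((n_tuples, n_codes), dtype=np.int64)
    t_idx = np.arange(n_tuples)
    for row in np.nonzero(mask_h)[0]:
        np.add.at(counts_h, (t_idx, codes[row]), 1)
    for row in np.nonzero(mask_c)[0]:
        np.add.at(counts_c, (t_idx, codes[row]), 1)
    freq_h = counts_h / n_h
    freq_c = counts_c / n_c
    contrast = freq_h - freq_c

    for class_label, sign in (("healthy", 1.0), ("cancer", -1.0)):
        t_sel, code_sel = np.nonzero(sign * contrast >= delta_min)
        patterns = [
            OrderingPattern(
                feature=features[t],
                permutation=_decode(int(c), k),
                class_label=class_label,
                weight=float(sign * contrast[t, c]),
                freq_healthy=float(freq_h[t, c]),
                freq_cancer=float(freq_c[t, c]),
            )
            for t, c in zip(t_sel, code_sel)
        ]
        patterns.sort(
            key=lambda p: (-p.weight, p.feature.region_id, p.feature.start_index, p.permutation)
        )
        patterns = patterns[:max_patterns_per_class]
        if class_label == "healthy":
            model.healthy_patterns = patterns
        else:
            model.cancer_patterns = patterns

    if model.n_patterns == 0:
        logger.warning(
            "no pattern reached the frequency contrast delta_min=%.3g; "
            "scoring with this model yields all-zero scores",
            delta_min,
        )
    return model


def score_samples(model: PatternModel, dmas: DMASMatrix) -> pd.DataFrame:
    """H-, C- and D-scores per sample; z left unset (see normalize_scores).

    h_score sums the weights of healthy-specific patterns whose permutation
    matches the sample's observed ordering on that tuple; c_score likewise
    for cancer-specific patterns; d_score = h_score - c_score.
    """
    n = len(dmas.sample_ids)
    h = np.zeros(n)
    c = np.zeros(n)
    all_patterns = model.healthy_patterns + model.cancer_patterns
    if all_patterns:
        features = [p.feature for p in all_patterns]
        cols = _feature_columns(features, dmas.window_ids)
        codes = _ordering_codes(dmas.values, cols, model.k)
        base = model.k ** np.arange(model.k, dtype=np.int64)
        for j, p in enumerate(all_patterns):
            target = int(np.asarray(p.permutation) @ base)
            matched = codes[:, j] == target
            if p.class_label == "healthy":
                h += p.weight * matched
            else:
                c += p.weight * matched
    return pd.DataFrame(
        {
            "sample_id": list(dmas.sample_ids),
            "h_score": h,
            "c_score": c,
            "d_score": h - c,
            "z": np.nan,
        }
    )


def normalize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Standardize d_score within the batch (mean 0, sd 1 with n-1 denominator).

    Samples normalized together must come from the same scoring batch.  A
    degenerate batch (sd == 0) maps to all-zero z rather than NaN.
    """
    if len(scores) < 2:
        raise ValidationError("normalization needs >= 2 samples in the batch")
    d = scores["d_score"].to_numpy(dtype=float)
    sd = d.std(ddof=1)
    out = scores.copy()
    out["z"] = np.zeros_like(d) if sd == 0 else (d - d.mean()) / sd
    return out


def classify(z: float, cutoff: float = 0.0) -> str:
    """Call a sample healthy (z above cutoff) or cancer (at or below).

    Low z means high cancer risk; the boundary goes to the risk class.
    """
    return "healthy" if z > cutoff else "cancer"
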