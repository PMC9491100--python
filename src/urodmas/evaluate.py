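"""Cross-validation, ensemble scoring and evaluation statistics.

Training uses stratified 10-fold cross-validation: each fold's model is
mined on the other nine folds and scores its held-out samples, which are
z-normalized within that held-out subset; the pooled z scores over all
folds feed one ROC (the integrated AUC).  External cohorts are scored by
all ten fold models (per-model z-normalization within the external batch)
and a sample's final z is the mean of its ten per-model z values.

Healthy is the ROC positive class: low z indicates high cancer risk, so an
AUC of 1 means every healthy-like sample scored above every cancer-like
one.  Confidence intervals use the DeLong variance of the Mann-Whitney
AUC; the reported cutoff maximizes Youden's J.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import mine_patterns, normalize_scores, score_samples
from .types import DMASMatrix, PatternModel, ValidationError, WindowCatalog


@dataclass
class FoldAssignment:
    """Stratified mapping sample_id -> fold index."""

    n_folds: int
    assignment: dict[str, int]
    seed: int

    def fold_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    n_pos: int
    n_neg: int


@dataclass
class CVResult:
    scores: pd.DataFrame  # sample_id, fold, h_score, c_score, d_score, z
    models: list[PatternModel]
    folds: FoldAssignment
    roc: ROCResult


def stratified_folds(labels: Mapping[str, str], n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Assign samples to folds, stratified by class, sizes differing by <= 1.

    Each class is shuffled and dealt round-robin; the second class starts
    dealing where the first left off so overall fold sizes stay balanced.
    """
    if n_folds < 2:
        raise ValidationError(f"n_folds must be >= 2, got {n_folds}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for cls in sorted(set(labels.values())):
        members = sorted(s for s, c in labels.items() if c == cls)
        if len(members) < n_folds and len(set(labels.values())) > 1:
            raise ValidationError(
                f"class {cls!r} has {len(members)} samples; need >= n_folds={n_folds} "
                "so every training split contains both classes"
            )
        rng.shuffle(members)
        for i, s in enumerate(members):
            assignment[s] = (offset + i) % n_folds
        offset += len(members)
    return FoldAssignment(n_folds, assignment, seed)


def cross_validate(
    dmas: DMASMatrix,
    labels: Mapping[str, str],
    catalog: WindowCatalog,
    n_folds: int = 10,
    seed: int = 0,
    k: int = 3,
    delta_min: float = 0.5,
    max_patterns_per_class: int = 2000,
) -> CVResult:
    """Stratified k-fold training; every sample scored exactly once held out."""
    missing = [s for s in dmas.sample_ids if s not in labels]
    if missing:
        raise ValidationError(f"samples without labels: {missing[:10]}")
    folds = stratified_folds({s: labels[s] for s in dmas.sample_ids}, n_folds, seed)
    models: list[PatternModel] = []
    per_fold: list[pd.DataFrame] = []
    for fold in range(n_folds):
        held = [s for s in dmas.sample_ids if folds.assignment[s] == fold]
        train = [s for s in dmas.sample_ids if folds.assignment[s] != fold]
        train_classes = {labels[s] for s in train}
        if len(train_classes) < 2:
            raise ValidationError(f"training split of fold {fold} lacks a class")
        model = mine_patterns(
            dmas.subset_samples(train),
            labels,
            catalog,
            k=k,
            delta_min=delta_min,
            max_patterns_per_class=max_patterns_per_class,
            metadata={"fold": fold, "seed": seed, "n_train": len(train)},
        )
        models.append(model)
        scored = normalize_scores(score_samples(model, dmas.subset_samples(held)))
        scored.insert(1, "fold", fold)
        per_fold.append(scored)
    scores = pd.concat(per_fold, ignore_index=True)
    # keep the cohort's original sample order
    scores = scores.set_index("sample_id").loc[list(dmas.sample_ids)].reset_index()
    roc = roc_auc(
        scores["z"].to_numpy(),
        np.array([labels[s] == "healthy" for s in scores["sample_id"]]),
    )
    return CVResult(scores=scores, models=models, folds=folds, roc=roc)


def ensemble_score(models: Sequence[PatternModel], dmas: DMASMatrix) -> pd.DataFrame:
    """Score an external batch with every model; final z = mean of per-model z.

    Each model's raw D-scores are z-normalized across the external batch
    before averaging, so models with different pattern counts contribute on
    a common scale.  Order of models does not matter.
    """
    if not models:
        raise ValidationError("ensemble needs at least one model")
    z_cols = []
    for model in models:
        scored = normalize_scores(score_samples(model, dmas))
        z_cols.append(scored["z"].to_numpy())
    z = np.column_stack(z_cols)
    return pd.DataFrame(
        {
            "sample_id": list(dmas.sample_ids),
            "z": z.mean(axis=1),
            **{f"z_model_{i}": z[:, i] for i in range(z.shape[1])},
        }
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) + 0.5 P(tie), via midranks."""
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """Variance of the Mann-Whitney AUC by the DeLong structural components."""
    m, n = len(pos), len(neg)
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)  # per-positive
    v01 = psi.mean(axis=0)  # per-negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_auc(z_scores: Sequence[float], is_positive: Sequence[bool], alpha: float = 0.05) -> ROCResult:
    """Mann-Whitney AUC with DeLong 95% CI and the Youden-optimal cutoff.

    ``is_positive`` flags the high-score (healthy-like) class.  The cutoff
    is the observed z maximizing sensitivity + specificity - 1, calling
    healthy strictly above the cutoff; ties go to the smaller cutoff.
    """
    z = np.asarray(z_scores, dtype=float)
    mask = np.asarray(is_positive, dtype=bool)
    pos, neg = z[mask], z[~mask]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("ROC needs at least one sample in each class")
    auc = _mann_whitney_auc(pos, neg)
    se = float(np.sqrt(_delong_variance(pos, neg)))
    zq = float(stats.norm.ppf(1 - alpha / 2))
    ci_low = max(0.0, auc - zq * se)
    ci_high = min(1.0, auc + zq * se)

    best_cutoff, best_j = np.nan, -np.inf
    for c in np.sort(np.unique(z)):
        sens = float((pos > c).mean())
        spec = float((neg <= c).mean())
        j = sens + spec - 1
        if j > best_j:  # strict: ties keep the smaller (earlier) cutoff
            best_j, best_cutoff = j, float(c)
    return ROCResult(auc, ci_low, ci_high, best_cutoff, len(pos), len(neg))


def roc_curve_points(z_scores: Sequence[float], is_positive: Sequence[bool]) -> pd.DataFrame:
    """Empirical ROC curve (1-specificity, sensitivity) over all thresholds."""
    z = np.asarray(z_scores, dtype=float)
    mask = np.asarray(is_positive, dtype=bool)
    pos, neg = z[mask], z[~mask]
    cuts = np.concatenate([[np.inf], np.sort(np.unique(z))[::-1], [-np.inf]])
    rows = [
        {"cutoff": float(c), "fpr": float((neg > c).mean()), "tpr": float((pos > c).mean())}
        for c in cuts
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group contrasts and longitudinal trajectories
# ---------------------------------------------------------------------------

def compare_groups(z_a: Sequence[float], z_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two z-score groups.

    Exact null distribution for small groups (both n <= 8, no ties),
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(z_a, dtype=float)
    b = np.asarray(z_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    small = max(len(a), len(b)) <= 8
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if small and not has_ties else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def longitudinal_deltas(scores: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-patient z trajectories for patients sampled at >= 2 timepoints.

    Returns one row per patient with the ordered timepoints, the matching z
    values, and whether the final z strictly exceeds the immediately
    preceding one (the expected direction when tumor burden clears).
    """
    merged = scores.merge(
        sheet[["sample_id", "patient_id", "timepoint", "cohort"]], on="sample_id", how="left"
    )
    merged = merged.dropna(subset=["patient_id", "timepoint"])
    rows = []
    for patient, sub in merged.groupby("patient_id"):
        if len(sub) < 2:
            continue
        sub = sub.sort_values("timepoint")
        zs = sub["z"].to_list()
        rows.append(
            {
                "patient_id": patient,
                "n_timepoints": len(sub),
                "timepoints": ",".join(str(int(t)) for t in sub["timepoint"]),
                "cohorts": ",".join(sub["cohort"]),
                "z_values": ",".join(format(z, ".6g") for z in zs),
                "z_previous": zs[-2],
                "z_final": zs[-1],
                "increased": bool(zs[-1] > zs[-2]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "n_timepoints",
            "timepoints",
            "cohorts",
            "z_values",
            "z_previous",
            "z_final",
            "increased",
        ],
    )
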