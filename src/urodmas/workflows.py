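"""End-to-end study workflows composed from the pipeline stages.

``run_synthetic_study`` mirrors the full design: generate a panel and
cohorts, window and score them, train by 10-fold cross-validation on
healthy vs primary, ensemble-score the surveillance cohorts (recurrent vs
non-recurrent), call the benign cohort at the default cutoff, and compute
cohort contrasts and per-patient longitudinal trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .dmas import compute_dmas
from .evaluate import (
    CVResult,
    ROCResult,
    compare_groups,
    cross_validate,
    ensemble_score,
    longitudinal_deltas,
    roc_auc,
)
from .patterns import classify
from .simulate import CohortData, Panel, SimConfig, TruthTable, plant_truth, simulate_cohorts, simulate_panel
from .types import CountMatrix, DMASMatrix, ValidationError, WindowCatalog
from .windows import aggregate_counts, build_windows

# cohort -> training / ROC class
COHORT_CLASS = {
    "healthy": "healthy",
    "benign": "healthy",
    "primary": "cancer",
    "recurrent": "cancer",
    "non_recurrent": "cancer",
}


def dataset_to_dmas(catalog: WindowCatalog, data: CohortData) -> tuple[CountMatrix, DMASMatrix]:
    """Aggregate a simulated dataset's site counts and compute DMAS."""
    counts = aggregate_counts(catalog, data.reports())
    return counts, compute_dmas(counts)


@dataclass
class StudyResult:
    config: SimConfig
    catalog: WindowCatalog
    truth: TruthTable
    sheet: pd.DataFrame  # all cohorts
    cv: CVResult  # healthy vs primary cross-validation
    validation_scores: pd.DataFrame  # ensemble z for recurrent + non_recurrent
    validation_roc: ROCResult
    benign_scores: Optional[pd.DataFrame]  # ensemble z + call for benign cohort
    contrasts: pd.DataFrame  # pairwise cohort rank-sum tests
    longitudinal: pd.DataFrame


def run_synthetic_study(
    config: SimConfig,
    n_folds: int = 10,
    k: int = 3,
    delta_min: float = 0.5,
    max_patterns_per_class: int = 2000,
    cutoff: float = 0.0,
) -> StudyResult:
    """The complete synthetic study: train, validate, monitor, contrast.

    Training cohorts (healthy + primary) are drawn from ``config.seed``;
    the surveillance and benign cohorts are an independent draw (same
    panel and planted truth, seed offset by one) so validation never sees
    training noise.
    """
    sizes = config.cohort_sizes
    for cohort in ("healthy", "primary"):
        if sizes.get(cohort, 0) < n_folds:
            raise ValidationError(
                f"need >= {n_folds} {cohort} samples for {n_folds}-fold CV"
            )
    panel = simulate_panel(config)
    truth = plant_truth(panel, config)
    catalog = build_windows(panel.regions, config.window_length)

    train_data = simulate_cohorts(
        panel,
        truth,
        config,
        cohorts={c: sizes[c] for c in ("healthy", "primary")},
        rng=np.random.default_rng(config.seed + 2),
    )
    _, train_dmas = dataset_to_dmas(catalog, train_data)
    labels = {e.sample_id: COHORT_CLASS[e.cohort] for e in train_data.entries}
    cv = cross_validate(
        train_dmas,
        labels,
        catalog,
        n_folds=n_folds,
        seed=config.seed,
        k=k,
        delta_min=delta_min,
        max_patterns_per_class=max_patterns_per_class,
    )

    external_cohorts = {
        c: sizes[c] for c in ("recurrent", "non_recurrent", "benign") if sizes.get(c, 0) > 0
    }
    validation_scores = pd.DataFrame(columns=["sample_id", "z"])
    benign_scores = None
    validation_roc = None
    longitudinal = pd.DataFrame()
    sheets = [train_data.sheet()]
    cohort_z: dict[str, np.ndarray] = {}
    if external_cohorts:
        ext_data = simulate_cohorts(
            panel,
            truth,
            config,
            cohorts=external_cohorts,
            rng=np.random.default_rng(config.seed + 1 + 2),
        )
        sheets.append(ext_data.sheet())
        _, ext_dmas = dataset_to_dmas(catalog, ext_data)
        surveillance = [
            e.sample_id for e in ext_data.entries if e.cohort in ("recurrent", "non_recurrent")
        ]
        if surveillance:
            validation_scores = ensemble_score(cv.models, ext_dmas.subset_samples(surveillance))
            cohort_of = {e.sample_id: e.cohort for e in ext_data.entries}
            validation_scores["cohort"] = [cohort_of[s] for s in validation_scores["sample_id"]]
            if {"recurrent", "non_recurrent"} <= set(validation_scores["cohort"]):
                validation_roc = roc_auc(
                    validation_scores["z"],
                    validation_scores["cohort"] == "non_recurrent",
                )
        if any(e.cohort == "benign" for e in ext_data.entries):
            # benign samples are scored in one batch with the surveillance
            # cohorts so the batch normalization sees the tumor-signal range
            combined = ensemble_score(cv.models, ext_dmas)
            cohort_of = {e.sample_id: e.cohort for e in ext_data.entries}
            combined["cohort"] = [cohort_of[s] for s in combined["sample_id"]]
            benign_scores = combined[combined["cohort"] == "benign"][
                ["sample_id", "z", "cohort"]
            ].reset_index(drop=True)
            benign_scores["call"] = [classify(z, cutoff) for z in benign_scores["z"]]
        if len(validation_scores):
            score_cols = validation_scores[["sample_id", "z"]]
            longitudinal = longitudinal_deltas(score_cols, ext_data.sheet())

    sheet = pd.concat(sheets, ignore_index=True)

    # pairwise cohort contrasts on whichever z each cohort received
    cv_cohort = {e.sample_id: e.cohort for e in train_data.entries}
    for cohort in ("healthy", "primary"):
        ids = [s for s in cv.scores["sample_id"] if cv_cohort[s] == cohort]
        if ids:
            cohort_z[cohort] = (
                cv.scores.set_index("sample_id").loc[ids, "z"].to_numpy()
            )
    for cohort in ("recurrent", "non_recurrent"):
        sub = validation_scores[validation_scores.get("cohort", pd.Series(dtype=str)) == cohort]
        if len(sub):
            cohort_z[cohort] = sub["z"].to_numpy()
    if benign_scores is not None and len(benign_scores):
        cohort_z["benign"] = benign_scores["z"].to_numpy()
    rows = []
    for a, b in combinations(sorted(cohort_z), 2):
        if len(cohort_z[a]) and len(cohort_z[b]):
            rows.append(
                {
                    "cohort_a": a,
                    "cohort_b": b,
                    "n_a": len(cohort_z[a]),
                    "n_b": len(cohort_z[b]),
                    "median_a": float(np.median(cohort_z[a])),
                    "median_b": float(np.median(cohort_z[b])),
                    "p_value": compare_groups(cohort_z[a], cohort_z[b]),
                }
            )
    contrasts = pd.DataFrame(
        rows, columns=["cohort_a", "cohort_b", "n_a", "n_b", "median_a", "median_b", "p_value"]
    )

    return StudyResult(
        config=config,
        catalog=catalog,
        truth=truth,
        sheet=sheet,
        cv=cv,
        validation_scores=validation_scores,
        validation_roc=validation_roc,
        benign_scores=benign_scores,
        contrasts=contrasts,
        longitudinal=longitudinal,
    )
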