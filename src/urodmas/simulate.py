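"""Synthetic capture panels, cytosine reports and sample sheets.

The generator emulates the structure of a promoter-targeted bisulfite
capture experiment on urine sediment DNA: a panel of non-overlapping
capture regions, cytosines scattered through them, per-site read coverage
(including uncovered sites), and class-dependent window methylation.

Per window w the baseline methylation level beta_w is drawn from a bimodal
promoter-like mixture (mostly low methylation with a hypermethylated
minority).  A fraction rho of windows is differentially methylated: their
tumor level is beta_w shifted by the effect size toward hypermethylation
(the dominant direction for promoter CpG islands in tumors).  A sample of
tumor purity q mixes the two levels, mu = q * beta_tumor + (1-q) * beta_w;
its realized per-window methylation probability is Beta-distributed around
mu with concentration kappa, so inter-sample variability persists at any
sequencing depth.  Site coverage is Poisson with an independent fraction
of sites forced to zero coverage; methylated counts are Binomial.

Tumor purity models the exfoliated-tumor-cell content of urine: full for
primary/recurrent disease, a small residue for non-recurrent patients
under surveillance, zero for healthy and benign donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from . import io as uio
from .types import CaptureRegion, CytosineRecord, SampleSheetEntry, ValidationError
from .windows import build_windows

_COHORT_PREFIX = {
    "healthy": "H",
    "primary": "P",
    "recurrent": "R",
    "non_recurrent": "N",
    "benign": "B",
}

# rough cohort demographics used for covariate draws (age mean/sd,
# P(female), P(smoker)); cancer cohorts additionally get stage and grade
_COVARIATES = {
    "healthy": (55, 9, 0.78, 0.18),
    "primary": (72, 12, 0.20, 0.20),
    "recurrent": (75, 11, 0.10, 0.14),
    "non_recurrent": (68, 11, 0.21, 0.26),
    "benign": (68, 17, 0.20, 0.0),
}
_STAGES = ("Ta", "T1", "T2", "T3")
_STAGE_P = (0.37, 0.30, 0.26, 0.07)


@dataclass
class SimConfig:
    """Generator settings; the defaults are the reference study conditions."""

    n_regions: int = 200
    region_length_range: tuple[int, int] = (500, 3000)
    site_spacing: float = 15.0  # mean bp between cytosines
    mean_depth: float = 30.0  # mean per-site coverage
    zero_coverage_fraction: float = 0.1  # sites with no reads at all
    dm_window_fraction: float = 0.1  # rho: fraction of DM windows
    effect_size: float = 0.4  # delta: methylation-probability shift
    concentration: float = 30.0  # kappa: beta overdispersion
    hypo_fraction: float = 0.0  # fraction of DM windows shifted down instead
    window_length: int = 500
    n_chroms: int = 4
    tumor_purity: dict[str, float] = field(
        default_factory=lambda: {
            "healthy": 0.0,
            "primary": 0.7,
            "recurrent": 0.7,
            "non_recurrent": 0.15,
            "benign": 0.0,
        }
    )
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "healthy": 40,
            "primary": 40,
            "recurrent": 21,
            "non_recurrent": 19,
            "benign": 5,
        }
    )
    seed: int = 1

    def __post_init__(self) -> None:
        for name, p in [
            ("zero_coverage_fraction", self.zero_coverage_fraction),
            ("dm_window_fraction", self.dm_window_fraction),
            ("hypo_fraction", self.hypo_fraction),
            *((f"tumor_purity[{c}]", q) for c, q in self.tumor_purity.items()),
        ]:
            if not 0 <= p <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if self.effect_size < 0 or self.effect_size > 1:
            raise ValidationError("effect_size must be in [0, 1]")
        if self.region_length_range[0] > self.region_length_range[1]:
            raise ValidationError("region_length_range must be (low, high)")


@dataclass
class Panel:
    """A simulated capture panel with its cytosine sites."""

    regions: list[CaptureRegion]
    site_chrom: np.ndarray  # per-site chromosome
    site_pos: np.ndarray  # 1-based positions
    site_strand: np.ndarray
    site_region: np.ndarray  # index into regions

    @property
    def n_sites(self) -> int:
        return len(self.site_pos)


@dataclass
class TruthTable:
    """Planted per-window methylation levels and differential flags.

    Units cover all tiled windows plus each region's sub-window remainder
    (remainders carry baseline signal only and are dropped downstream).
    ``window_ids`` aligns the first len(window_ids) units with the window
    catalog built at ``window_length``.
    """

    window_ids: list[str]
    beta_base: np.ndarray  # per unit
    beta_tumor: np.ndarray
    is_dm: np.ndarray  # bool per unit
    direction: np.ndarray  # +1 hyper, -1 hypo, 0 not DM
    site_unit: np.ndarray  # per-site unit index

    def frame(self) -> pd.DataFrame:
        n = len(self.window_ids)
        return pd.DataFrame(
            {
                "window_id": self.window_ids,
                "beta_base": self.beta_base[:n],
                "beta_tumor": self.beta_tumor[:n],
                "is_dm": self.is_dm[:n],
                "direction": self.direction[:n],
            }
        )


@dataclass
class CohortData:
    """Simulated per-sample site-level counts plus the sample sheet."""

    entries: list[SampleSheetEntry]
    panel: Panel
    methyl: np.ndarray  # samples x sites
    unmethyl: np.ndarray

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def sheet(self) -> pd.DataFrame:
        return uio.sheet_to_frame(self.entries)

    def report_frame(self, sample_id: str) -> pd.DataFrame:
        """One sample's cytosine report as a DataFrame (all contexts CpG)."""
        row = self.sample_ids.index(sample_id)
        return pd.DataFrame(
            {
                "chrom": self.panel.site_chrom,
                "pos": self.panel.site_pos,
                "strand": self.panel.site_strand,
                "n_meth": self.methyl[row],
                "n_unmeth": self.unmethyl[row],
                "context": "CpG",
            }
        )

    def reports(self) -> dict[str, pd.DataFrame]:
        return {s: self.report_frame(s) for s in self.sample_ids}

    def iter_records(self, sample_id: str) -> Iterator[CytosineRecord]:
        row = self.sample_ids.index(sample_id)
        for i in range(self.panel.n_sites):
            yield CytosineRecord(
                str(self.panel.site_chrom[i]),
                int(self.panel.site_pos[i]),
                str(self.panel.site_strand[i]),
                int(self.methyl[row, i]),
                int(self.unmethyl[row, i]),
                "CpG",
            )

    def write_reports(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sid in self.sample_ids:
            path = directory / f"{sid}.cytosine_report.tsv"
            uio.write_cytosine_report(path, self.iter_records(sid))
            paths[sid] = path
        return paths


def simulate_panel(config: SimConfig, rng: Optional[np.random.Generator] = None) -> Panel:
    """Draw a non-overlapping capture panel and its cytosine sites.

    Region lengths are uniform in ``region_length_range``; regions are
    spread over ``n_chroms`` chromosomes with gaps between neighbors.
    Cytosines are placed with exponential spacing (mean ``site_spacing``)
    inside regions; every region carries at least one site.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.region_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_regions)
    gaps = rng.integers(500, 2001, size=config.n_regions)
    cursors = {f"chr{c + 1}": 1000 for c in range(config.n_chroms)}
    regions = []
    for i in range(config.n_regions):
        chrom = f"chr{(i % config.n_chroms) + 1}"
        start = cursors[chrom]
        end = start + int(lengths[i])
        regions.append(CaptureRegion(chrom, start, end, f"reg{i:05d}"))
        cursors[chrom] = end + int(gaps[i])
    regions.sort(key=lambda r: (r.chrom, r.start))

    chroms, poss, strands, region_idx = [], [], [], []
    for ri, region in enumerate(regions):
        offsets = np.cumsum(rng.exponential(config.site_spacing, size=max(4, int(3 * region.length / config.site_spacing))))
        offsets = np.unique(offsets.astype(np.int64))
        offsets = offsets[offsets < region.length]
        if len(offsets) == 0:
            offsets = np.array([0], dtype=np.int64)
        pos = region.start + offsets + 1  # 1-based
        chroms.append(np.full(len(pos), region.chrom, dtype=object))
        poss.append(pos)
        strands.append(np.where(rng.random(len(pos)) < 0.5, "+", "-").astype(object))
        region_idx.append(np.full(len(pos), ri, dtype=np.int64))
    return Panel(
        regions=regions,
        site_chrom=np.concatenate(chroms),
        site_pos=np.concatenate(poss),
        site_strand=np.concatenate(strands),
        site_region=np.concatenate(region_idx),
    )


def plant_truth(panel: Panel, config: SimConfig, rng: Optional[np.random.Generator] = None) -> TruthTable:
    """Assign baseline and tumor methylation levels to every window.

    Baselines come from the promoter-like mixture 0.8 Beta(1, 10) +
    0.2 Beta(10, 1).  A fraction ``dm_window_fraction`` of tiled windows is
    differentially methylated with tumor level clamped to [0.02, 0.98].
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    catalog = build_windows(panel.regions, config.window_length)
    window_ids = catalog.window_ids

    # units: tiled windows first (catalog order), then per-region remainders
    unit_of_window: dict[tuple[int, int], int] = {}
    region_index = {r.region_id: i for i, r in enumerate(panel.regions)}
    for u, w in enumerate(catalog.windows):
        unit_of_window[(region_index[w.region_id], w.index_in_region)] = u
    n_units = len(window_ids)
    remainder_unit = {}
    for ri, region in enumerate(panel.regions):
        n_win = region.length // config.window_length
        if region.length % config.window_length or n_win == 0:
            remainder_unit[ri] = n_units
            n_units += 1

    beta_base = np.where(
        rng.random(n_units) < 0.8,
        rng.beta(1, 10, size=n_units),
        rng.beta(10, 1, size=n_units),
    )
    is_dm = np.zeros(n_units, dtype=bool)
    is_dm[: len(window_ids)] = rng.random(len(window_ids)) < config.dm_window_fraction
    direction = np.zeros(n_units, dtype=np.int64)
    hypo = rng.random(n_units) < config.hypo_fraction
    direction[is_dm] = np.where(hypo[is_dm], -1, 1)
    beta_tumor = beta_base.copy()
    shifted = beta_base + direction * config.effect_size
    beta_tumor[is_dm] = np.clip(shifted[is_dm], 0.02, 0.98)

    site_unit = np.empty(panel.n_sites, dtype=np.int64)
    for i in range(panel.n_sites):
        ri = int(panel.site_region[i])
        region = panel.regions[ri]
        w = (int(panel.site_pos[i]) - 1 - region.start) // config.window_length
        n_win = region.length // config.window_length
        if w >= n_win:
            site_unit[i] = remainder_unit[ri]
        else:
            site_unit[i] = unit_of_window[(ri, w)]
    return TruthTable(window_ids, beta_base, beta_tumor, is_dm, direction, site_unit)


def _covariates(cohort: str, rng: np.random.Generator) -> dict:
    age_mu, age_sd, p_female, p_smoke = _COVARIATES[cohort]
    cov = {
        "age": float(int(np.clip(rng.normal(age_mu, age_sd), 20, 95))),
        "sex": "female" if rng.random() < p_female else "male",
        "smoking": "yes" if rng.random() < p_smoke else "no",
        "stage": None,
        "grade": None,
    }
    if cohort in ("primary", "recurrent"):
        cov["stage"] = _STAGES[rng.choice(4, p=_STAGE_P)]
        cov["grade"] = "high" if rng.random() < 0.85 else "low"
    return cov


def simulate_cohorts(
    panel: Panel,
    truth: TruthTable,
    config: SimConfig,
    cohorts: Optional[Mapping[str, int]] = None,
    rng: Optional[np.random.Generator] = None,
    n_linked_patients: int = 6,
) -> CohortData:
    """Draw per-sample site-level counts for the requested cohorts.

    ``cohorts`` maps cohort name to sample count (default: the config's
    cohort sizes).  When both the recurrent and non-recurrent cohorts are
    drawn, up to ``n_linked_patients`` patients contribute one sample to
    each (timepoints 1 and 2), enabling longitudinal contrasts.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    sizes = dict(cohorts) if cohorts is not None else dict(config.cohort_sizes)
    for c in sizes:
        if c not in _COHORT_PREFIX:
            raise ValidationError(f"unknown cohort {c!r}")

    entries: list[SampleSheetEntry] = []
    purities: list[float] = []
    patient_serial = 0
    n_link = min(n_linked_patients, sizes.get("recurrent", 0), sizes.get("non_recurrent", 0))
    for cohort in _COHORT_PREFIX:  # fixed draw order for determinism
        n = sizes.get(cohort, 0)
        for i in range(n):
            sid = f"{_COHORT_PREFIX[cohort]}{i + 1:03d}"
            if cohort == "recurrent" and i < n_link:
                patient, tp = f"PT{i + 1:03d}", 1
            elif cohort == "non_recurrent" and i < n_link:
                patient, tp = f"PT{i + 1:03d}", 2
            else:
                patient_serial += 1
                patient, tp = f"PU{patient_serial:04d}", 1
            entries.append(
                SampleSheetEntry(
                    sample_id=sid,
                    cohort=cohort,
                    patient_id=patient,
                    timepoint=tp,
                    **_covariates(cohort, rng),
                )
            )
            purities.append(config.tumor_purity.get(cohort, 0.0))

    n_samples = len(entries)
    n_units = len(truth.beta_base)
    q = np.array(purities)[:, None]
    mu = q * truth.beta_tumor[None, :] + (1 - q) * truth.beta_base[None, :]
    mu = np.clip(mu, 1e-4, 1 - 1e-4)
    kappa = config.concentration
    p_unit = rng.beta(mu * kappa, (1 - mu) * kappa, size=(n_samples, n_units))
    p_site = p_unit[:, truth.site_unit]

    coverage = rng.poisson(config.mean_depth, size=(n_samples, panel.n_sites))
    coverage[rng.random((n_samples, panel.n_sites)) < config.zero_coverage_fraction] = 0
    methyl = rng.binomial(coverage, p_site)
    unmethyl = coverage - methyl
    return CohortData(entries=entries, panel=panel, methyl=methyl, unmethyl=unmethyl)


def simulate_dataset(
    config: SimConfig, cohorts: Optional[Mapping[str, int]] = None
) -> tuple[Panel, TruthTable, CohortData]:
    """Panel + truth + cohorts in one call, all seeded from ``config.seed``."""
    panel = simulate_panel(config)
    truth = plant_truth(panel, config)
    data = simulate_cohorts(panel, truth, config, cohorts=cohorts)
    return panel, truth, data
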