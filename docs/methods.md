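# Methods

## Scope and data model

`urodmas` consumes three inputs: a capture panel (BED, 0-based half-open
intervals), per-sample genome-wide cytosine reports (7 columns: chromosome,
1-based position, strand, methylated count, unmethylated count, context,
trinucleotide — the layout emitted by standard bisulfite methylation
extractors; the trinucleotide column is ignored), and a TSV sample sheet
mapping samples to cohorts (healthy / primary / recurrent / non_recurrent /
benign) and covariates. All downstream computation happens on typed
in-memory matrices oriented samples × windows.

By default all three cytosine contexts (CpG, CHG, CHH) on both strands are
retained; a CLI flag restricts aggregation to CpG only.

## Windowing

Each capture region of length L is tiled with `floor(L / 500)`
non-overlapping 500-bp windows anchored at the region start; the sub-500-bp
remainder at the 3' end is eliminated, and regions shorter than 500 bp
contribute nothing. Tiling anchors at the region start rather than at
genome-wide coordinates: the panel's regions are the natural analytic unit
and no other anchor is better motivated. A 1-based report position p falls
in the 0-based half-open window [s, e) iff s < p ≤ e. Sites outside every
retained window are dropped (tallied in the log); windows never covered by
any site still appear with counts (0, 0).

## The arctangent score

DMAS(i, j) = atan2(unmethyl(i, j), methyl(i, j)), in radians, double
precision. Properties relied on downstream, all enforced by tests:

- range [0, π/2]; exactly 0 for zero-coverage windows (atan2(0, 0) is
  pinned to 0 regardless of platform);
- strictly decreasing in the methylation rate at fixed coverage;
- scale-invariant in coverage (DMAS(k·u, k·m) = DMAS(u, m)), which is why
  no depth normalization is applied before scoring;
- near-perfect linear association with the rate (|r| > 0.99 over the grid
  of all count pairs with coverage 1–50).

The conventional rate `methyl / max(1e-10, methyl + unmethyl)` is provided
only for this comparison; the classifier never uses it.

## Ordering-pattern classifier

Features are sliding (stride-1) tuples of k consecutive retained windows
within a region; cross-region tuples are never formed. k defaults to 3
(configurable 2–4; k! growth makes larger k impractical and statistically
fragile). A sample's observation on a tuple is the permutation sorting its
DMAS values ascending, with ties broken by genomic order via a stable
sort — important because zero-coverage windows all carry DMAS 0, and the
tie rule keeps every observation total and deterministic.

Mining is exhaustive: for every tuple and every one of the k! permutations,
the frequency of that ordering is computed in each training class. A
(tuple, permutation) whose frequency contrast `f_target − f_other` reaches
`delta_min` (default 0.5) becomes a class-specific pattern with weight
equal to the contrast. Patterns are ranked by weight (ties by region id,
start index, permutation) and truncated to `max_patterns_per_class`
(default 2000). The contrast weight is the simplest quantity consistent
with summing weights at scoring time and automatically prioritizes
discriminative patterns; `delta_min = 0.5` keeps models small and, at
training-class sizes around 36–40, suppresses essentially all spurious
patterns under the null (see calibration below). Both are exposed as CLI
flags.

Scoring: H = Σ weights of matched healthy-specific patterns, C likewise
for cancer-specific, D = H − C. The z score standardizes D within the
batch of samples scored together (n−1 denominator; an sd-0 batch maps to
all-zero z rather than NaN). Only D is standardized — it is the quantity
that feeds the ROC. Classification at cutoff 0 assigns z > 0 to healthy
and z ≤ 0 to cancer; the boundary goes to the risk class.

## Cross-validation and ensemble

Folds are stratified by class (each class dealt round-robin after a seeded
shuffle; fold sizes differ by at most one) even though plain random folds
would usually work at 40+40 — stratification guarantees both classes in
every training split. Each fold's model scores its held-out samples,
normalized within that held-out subset; pooled z scores over all folds
give the integrated ROC. External cohorts are scored by all 10 fold
models; each model's D-scores are normalized across the external batch,
and the final z is the mean of the 10 per-model z values (mean rather
than sum; the two give identical ROC orderings).

The benign cohort is z-normalized in one batch together with the
surveillance cohorts, so the batch mean reflects the tumor-signal range;
normalizing five tumor-free samples alone would center them at z = 0 and
make the cutoff-0 call uninformative.

AUC is the Mann–Whitney probability P(z_healthy > z_cancer) + ½ P(tie),
with healthy as the positive (high-z) class. The 95% CI uses the DeLong
structural-components variance, clipped to [0, 1]; the reported cutoff
maximizes Youden's J with ties toward the smaller cutoff. Group contrasts
use the two-sided Wilcoxon rank-sum test (exact null distribution when
both groups have ≤ 8 samples and no ties, otherwise the normal
approximation with tie correction). Longitudinal reporting lists, per
patient with ≥ 2 timepoints, the ordered z values and whether the final z
strictly exceeds the immediately preceding one.

## Synthetic data generator

The generator emulates the structure of the targeted assay, and its
defaults are the reference study conditions: 200 regions of 500–3000 bp,
10% differentially methylated windows, effect size 0.4, beta concentration
κ = 30, mean depth 30, cohorts of 40 healthy / 40 primary / 21 recurrent /
19 non-recurrent / 5 benign, tumor purity 0.7 for primary and recurrent,
0.15 for non-recurrent (residual signal), 0 for healthy and benign.

Per-window baselines come from the bimodal promoter-like mixture
0.8·Beta(1, 10) + 0.2·Beta(10, 1); DM windows shift by the effect size
toward hypermethylation (the dominant direction for promoter CpG islands
in tumors; a flag plants a hypomethylated fraction instead), clamped to
[0.02, 0.98]. A sample of purity q has window mean μ = q·β_tumor +
(1−q)·β_base and a realized level drawn Beta(μκ, (1−μ)κ) — beta-binomial
rather than binomial sampling, so inter-sample variability persists at any
depth. Site coverage is Poisson(30) with an independent 10% of sites
forced to zero coverage; methylated counts are Binomial. Values not fixed
by the study design were chosen once on field-typical grounds: cytosines
every ~15 bp on average (dense, CpG-island-like promoter targets with all
contexts reported), 10% site dropout (uneven capture and low-input urine
DNA), regions spread over 4 chromosomes. Covariates (age, sex, smoking,
stage, grade) are drawn per cohort from rough clinical distributions; six
patients contribute one sample to each of the recurrent and non-recurrent
cohorts (timepoints 1 and 2) for longitudinal analysis.

What the generator does *not* emulate: genomic sequence context (site
placement is homogeneous within regions), spatial correlation of
methylation beyond the window level, batch/technical effects, bisulfite
conversion error, age- or sex-dependent methylation, and realistic
inter-patient heterogeneity of tumor profiles (all tumors share one truth
table). Passing the synthetic acceptance checks therefore demonstrates the
pipeline's correctness and its power under idealized planted signal, not
clinical performance on real urine cohorts.

## Problem sizes and calibration

The reference synthetic study (defaults above, seed 1) yields ~630
windows and runs in a few seconds; the pooled 10-fold CV AUC and the
ensemble surveillance AUC both reach 1.0, comfortably above the
scaled-down reproduction thresholds (0.960 and 0.915) asserted by the
acceptance suite. Null calibration uses 50 replicates of the same design
with purity 0 everywhere: at 36+36 training samples and delta_min 0.5 no
spurious pattern survives, models are empty, every z is 0 and the CV AUC
is exactly 0.5 with a degenerate CI — the 95% CI covers 0.5 in 50/50
replicates. Oracle-equivalence tests (per-site aggregation loop,
exhaustive pattern enumeration, brute-force AUC, quadratic nearest-gene
search) run on deliberately small random instances where the oracles are
exact.

## Numerical choices and degenerate inputs

- Ties in DMAS resolve by genomic order everywhere (stable sorts); model
  serialization is byte-deterministic for identical inputs.
- Empty pattern set (nothing reaches delta_min): warning, empty model,
  all-zero scores — not an error.
- sd = 0 scoring batches give all-zero z; batches of one sample are
  rejected.
- Overlapping capture regions are an error, not merged: window identity
  must stay unambiguous.
- Model JSON carries a `format_version` field; readers reject versions
  they do not understand.
- Floats round-trip exactly through TSV (shortest-repr serialization).

## Known limitations

- Pattern mining treats tuples independently; overlapping tuples share
  windows and their matched weights are correlated, so H/C scores are not
  sums of independent evidence.
- DeLong CIs are degenerate at AUC 1.0 (width 0); bootstrap CIs would be
  wider but are not the default.
- The nearest-gene assignment ignores strand and regulatory domains; it is
  a coordinate heuristic for exporting pattern gene lists, not a
  functional mapping.
- With very small folds (2–3 samples) the within-fold z normalization is
  coarse; 10-fold CV is intended for cohorts of tens of samples per class.
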