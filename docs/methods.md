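# Methods

This note documents the statistical procedures implemented in `dietmeth`,
their assumptions, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Consensus Δβ calling (`dietmeth.consensus`)

**Model.** For each study patient, the methylation change at every CpG is
the within-patient contrast

Δβ = mean(β_T2, β_T3 over available post-intervention timepoints) − β_T1,

so positive Δβ is a gain of methylation after the diet change. A CpG is
called *hyper* when at least `ceil(consensus_fraction × n_evaluable)`
patients individually show Δβ ≥ `delta_threshold`, and *hypo* symmetrically.
Defaults: threshold 0.10 (an absolute beta-scale difference, the standard
reading of "10 % methylation difference" for beta values, not a relative
change), consensus fraction 0.77. At the canonical design of 18 patients the
bar is ceil(13.86) = 14, identical to the "more than 3/4" reading; for other
n the ceiling of the configured fraction governs.

**Rationale.** The procedure is deliberately non-inferential: baseline blood
methylomes are heterogeneous across individuals, so a per-patient threshold
plus a consensus count is more faithful to "most patients changed at this
CpG" than a mean-difference test, and it needs no distributional assumption
on betas. The trade-off is that no per-CpG error rate is attached; the
planted-recovery tests quantify operating characteristics under the
generator's conditions instead.

**Direction consistency.** By default the consensus must be reached within
one direction (hyper and hypo exceedances counted separately); with
`require_direction_consistency=False`, patients qualify on |Δβ| and the call
direction is the majority sign among qualifying patients, ties giving no
call. With a consensus fraction above 0.5 and direction consistency on, a
probe can never be called in both directions.

**Missing data.** A patient missing one of T2/T3 contributes the single
available post-diet value (Δβ stays anchored at baseline); a patient with no
baseline sample is an error. At probe level, a patient with a missing value
is removed from both numerator and denominator, and the consensus bar is
recomputed on the evaluable count, so missingness does not penalise a probe.

**Subset summaries.** `subset_median_profile` pools all beta values of a
group's samples at the subset probes and reports the median per group
(study samples grouped by timepoint, controls by group label).
`subset_variance_test` reports, per group, the variance of *per-sample mean*
subset methylation — one number per participant, the natural scale for
"baseline profiles are more heterogeneous" — and a Brown–Forsythe
(median-centred Levene) dispersion test of each group against T1.
A `pooled=True` flag switches to pooled probe-level values, since the
per-sample-mean convention is a choice, not a mathematical necessity.

## Synthetic cohorts (`dietmeth.simulate`)

**What is emulated.** 18 patients × 3 blood timepoints, 60 healthy-blood
controls, liver panels with fibrosis grades 0–3 (40 per grade) plus 23
healthy-liver profiles. Per-probe baseline means follow a bimodal mixture
(40 % Beta(1.5, 12) low, 25 % Beta(2, 2) intermediate, 35 % Beta(12, 1.5)
high), mimicking the U-shaped beta distribution of methylation arrays.
A planted subset (default 100 hyper + 10 hypo) carries the diet signal:
carrier patients' T1 means sit `delta_effect` (default 0.20) away from a
common post-diet mean that T2, T3 and healthy blood share, so post-diet
profiles cluster with healthy controls and the planted Δβ is recovered with
the documented sign. Per-observation noise is Beta-distributed,
reparameterised from (mean, sd = 0.03) via the concentration
ν = m(1−m)/s² − 1, and all betas are clamped to [0.01, 0.99]: bounded
support rules out Gaussian noise.

**Carriers.** `consensus_carrier_fraction` (default 0.9) is realised as an
exact per-probe count, round(0.9 × 18) = 16 randomly chosen carrier
patients. An independent-Bernoulli reading would put a few percent of
planted probes below the 14-patient consensus bar *by construction*, making
the generator's own ground truth unrecoverable in principle; the exact-count
model keeps "90 % of patients carry the effect" true probe by probe while
still varying which patients carry it.

**Liver panels.** Grade-0 and healthy-liver profiles sit at the post-diet
(healthy) mean. Grade-g means move g × `grade_drift` (default 0.15) toward
the diseased baseline-like mean at planted sites, capped at that mean —
the shift is "toward", never past, so grade means are monotone in g and
saturate once the diseased mean is reached. Non-planted probes are
identically distributed across grades and tissues.

**Determinism.** One master seed feeds a single `numpy` Generator; draws
occur in a fixed documented order (baseline means → planted choice →
planted means → carriers → T1/T2/T3/healthy betas → manifest). The liver
panel uses the seed sequence `[seed, 1]` so it is reproducible without
replaying the blood draws. Identical config gives byte-identical TSVs.

**What is not emulated** — and therefore what passing tests do not show
about real arrays: probe cross-reactivity, SNP-affected probes, chip/batch
effects, cell-composition mixtures, spatial autocorrelation along the
genome, multi-gene probe annotations, and any real biological coupling
between feature categories and methylation level. Manifest categories are
drawn independently per probe from configurable frequencies (defaults
loosely EPIC-like, every category ≥ 5 %); `planted_feature_bias` can skew
planted probes toward chosen categories when an enrichment signal is wanted.

## Global summaries (`dietmeth.summaries`)

Median global methylation is computed per sample first and then aggregated
as the median of sample medians per group — chosen over a pooled median
because group-level displays compare per-sample distributions. PCA drops
probes with any missing value listwise (no imputation rule is defensible
for bounded betas), centres per probe, and fixes each component's sign by
making its largest-magnitude loading positive, so scores are reproducible
across backends; variance explained is relative to the total variance of
the centred matrix and defined as 0 when that total is 0. Clinical
correlations are Pearson per parameter with Bonferroni adjustment across
parameters (adjusted = min(1, m × raw)); zero-variance parameters are
reported NA with a warning.

## Enrichment (`dietmeth.enrichment`)

Within one annotation axis each probe carries exactly one category, so
observed counts partition the subset and FC = (obs/subset)/(bg/array) is
scale-invariant. "Expected by chance" is operationalised as size-matched
uniform resampling from the manifest background — the simplest null
consistent with the phrase — with two-sided empirical
p = (1 + #{draws with |log FC| ≥ observed}) / (n_draws + 1). Zero counts
enter the log fold change through a half-count continuity value
(count → max(count, 0.5)), which keeps extremity finite and scores an
FC of 0 by how depleted the count actually is relative to expectation;
without it, the modal zero draw of a rare category would register as
infinitely extreme. The background defaults to all manifest probes and is
overridable by passing a restricted manifest.

## Stratification (`dietmeth.stratify`)

Clustering is agglomerative with Ward linkage on Euclidean distances
between beta profiles (the common default for methylation matrices; both
are exposed as arguments), cut into k clusters, k defaulting to the number
of distinct grades. The cluster × grade contingency is tested with the
continuity-free Pearson Chi²; expected cells < 5 trigger a warning rather
than a silent switch of tests. The classifier is a gradient-boosted tree
ensemble with fixed hyperparameters (100 trees, learning rate 0.1, depth 2,
no subsampling) under stratified k-fold cross-validation — an AutoML search
would make the evaluation non-deterministic and would evaluate the search,
not the CpG panel. Capacity is kept modest because panels typically have
~10² features against ~10² samples; deeper ensembles overfit the folds and
bias the permutation-null AUC away from 0.5. Grade 3 is the positive class
and grade 0 the negative; intermediate grades are excluded from
classification. Accuracy is pooled over held-out folds at a 0.5 probability
threshold. The heatmap helper canonicalises by sorting sample and probe IDs
before linkage, making leaf orders invariant to input order.

## Clinical statistics (`dietmeth.clinstats`)

Missing values are imputed with the parameter's mean over all observed
values (pooled across patients and timepoints), which preserves the
parameter mean exactly. The parametric gate is Shapiro–Wilk per timepoint
at α = 0.05 — the smallest defensible condition; sphericity is not tested,
and a constant timepoint routes to the nonparametric branch. The parametric
branch is a one-way within-subject ANOVA (implemented directly from the
sums of squares and cross-checked against `pingouin.rm_anova` in the test
suite) with paired-t post hocs; the nonparametric branch is Friedman with
Wilcoxon signed-rank post hocs (zeros dropped, exact null for small n
without ties). Post hoc pairs are tested only when the omnibus p < α and
are Bonferroni-adjusted with m = 3, the three within-parameter comparisons;
no family-wide correction across parameters is applied, matching the
per-parameter reporting convention of clinical tables. Control comparisons
dispatch to Welch's t (normality in both groups) or two-sided Mann–Whitney;
Welch is used rather than Student's t because equal variances between
patients and controls cannot be assumed.

## Problem sizes

The bundled tests and the acceptance script run the generator at 300–5,000
probes with the full study design (18 patients, 60 controls, 40 liver
profiles per grade; smaller liver panels in unit fixtures), 200–1,000
resampling draws, and 200–1,000 simulation replicates for the calibration
checks. These sizes give stable estimates (binomial standard errors ≤ ~1.5
percentage points on the reported rates) while keeping a full run to a few
seconds.

## Known limitations

* The consensus caller attaches no per-CpG error control; its sensitivity
  and false-positive rate are characterised only under the generator's
  assumptions.
* Single-label manifests: real EPIC annotations allow one probe in several
  gene regions or regulatory features; enrichment here assumes mutually
  exclusive categories within an axis.
* The variance convention (per-sample means vs pooled values) changes the
  magnitude of reported group variances; both are available, only the
  convention is defaulted.
* PCA of near-constant matrices is dominated by noise; variance-explained
  figures are meaningful only when the planted (or real) signal is large
  relative to `noise_sd`.
* The classifier's cross-validation protocol is a documented substitute for
  an unspecified train/test split; absolute AUC values depend on it.
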