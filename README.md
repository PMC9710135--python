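# dietmeth

Longitudinal blood DNA-methylation analysis for diet-intervention studies,
built around a per-patient Δβ consensus caller and a fibrosis-grade
stratification evaluator.

## The problem

Diet change is the main treatment for non-alcoholic fatty liver disease
(NAFLD), and its effect shows up in the methylome of blood cells. A typical
study design profiles each patient's whole blood on an Illumina EPIC-style
array at baseline (T1) and at follow-ups after the intervention (T2, T3),
alongside healthy controls, and asks:

1. **Which CpG sites respond to the intervention?** Baseline methylomes are
   heterogeneous across patients, so a population-mean test is poorly
   suited. Instead, the change is computed *within* each patient,

   Δβ(CpG, patient) = mean(β_T2, β_T3) − β_T1,

   and a CpG is called diet-responsive when at least a consensus fraction
   of patients individually show |Δβ| ≥ a threshold in the same direction.
   The defaults — |Δβ| ≥ 0.10 in ≥ 77 % of patients, i.e. 14 of 18 — encode
   "a 10 % methylation difference in more than three quarters of
   participants".
2. **Where do the called CpGs sit?** Per feature category F (gene region,
   CpG-island relation, regulatory feature), the enrichment fold change is
   FC(F) = freq(F in called set) / freq(F on the array), with significance
   from size-matched uniform resampling.
3. **Does the blood-derived panel stratify liver disease?** Methylation at
   the called CpGs in liver biopsies is evaluated by unsupervised Ward
   clustering with a Chi² cluster-vs-grade test, and by a fixed-seed
   gradient-boosted classifier of fibrosis grade 0 vs 3 with
   cross-validated ROC AUC.

The package also computes global methylation summaries (per-sample medians,
PCA with a deterministic sign convention, clinical-parameter correlations)
and a longitudinal clinical-statistics engine (Shapiro-gated repeated-measures
ANOVA / Friedman with paired-t / Wilcoxon post hocs, Bonferroni-adjusted).

Because real study data of this kind are rarely public, `dietmeth.simulate`
generates a full synthetic cohort — 18 patients × 3 timepoints, healthy-blood
controls, fibrosis-graded liver panels — with a ground-truth ledger of
planted diet-responsive CpGs, so every stage is testable end to end.

## Worked example

```python
from dietmeth import (SimulationConfig, simulate_cohort, simulate_liver_panel,
                      compute_delta, call_sites)
from dietmeth.consensus import subset_variance_test
from dietmeth.stratify import classify_grades, cluster_and_test

cfg = SimulationConfig(seed=1)                      # study-design defaults
betas, sheet, manifest, truth = simulate_cohort(cfg)

result = call_sites(compute_delta(betas, sheet))
print(f"called {len(result.called_subset)} CpGs "
      f"({(result.call == 'hyper').sum()} hyper, {(result.call == 'hypo').sum()} hypo)")

print(subset_variance_test(betas, result.called_subset, sheet).round(6))

liver_betas, liver_sheet = simulate_liver_panel(cfg, truth)
panel = liver_betas.loc[result.called_subset]
clust = cluster_and_test(panel, liver_sheet)
print(f"cluster vs grade: chi2 = {clust.chi2_statistic:.1f}, "
      f"df = {clust.degrees_of_freedom}, p = {clust.p_value:.3g}")
rep = classify_grades(panel, liver_sheet, n_folds=5, seed=1)
print(f"grade 0 vs 3: mean CV AUC = {rep.mean_auc:.4f}, accuracy = {rep.accuracy:.3f}")
```

Output:

```
called 110 CpGs (100 hyper, 10 hypo)
                n  variance  p_vs_reference
group
T1             18  0.000021             NaN
T2             18  0.000006        0.046020
T3             18  0.000008        0.127362
healthy_blood  60  0.000005        0.000541
cluster vs grade: chi2 = 326.7, df = 9, p = 5.68e-65
grade 0 vs 3: mean CV AUC = 1.0000, accuracy = 1.000
```

The caller recovers exactly the 110 planted CpGs (100 gains, 10 losses of
methylation after the intervention); the variance of per-patient mean
methylation at those sites is highest at baseline, reflecting the planted
inter-patient heterogeneity; and the blood-derived panel separates the
synthetic liver panel both without supervision (Chi² on cluster × grade)
and as a grade-0-vs-3 classifier.

The same pipeline runs from the shell:

```bash
dietmeth simulate --outdir sim --seed 1
dietmeth call --betas sim/blood_betas.tsv --sheet sim/blood_samples.tsv --out calls.tsv
dietmeth enrich --subset calls.tsv --manifest sim/manifest.tsv --axis cgi_relation \
    --draws 1000 --seed 1 --out enrich.tsv
dietmeth stratify --betas sim/liver_betas.tsv --sheet sim/liver_samples.tsv \
    --panel calls.tsv --mode both --seed 1 --out report.json
```

## Data formats

All inputs are tab-separated UTF-8 text with `NA` for missing values:
a beta matrix (`probe_id` index column, one column per sample, values in
[0, 1]), a sample sheet (`sample_id, patient_id, timepoint, group, tissue,
fibrosis_grade`) and a probe manifest (`probe_id, chromosome, gene_id,
gene_region, cgi_relation, regulatory_feature`). See `docs/methods.md` for
the statistical model and all defaults.
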