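# neomer-mrd

Neomer-based molecular-residual-disease (MRD) profiling of plasma
cfDNA, built as a reusable analysis pipeline with a fully synthetic
study generator.

## The problem

After chemoradiotherapy for inoperable localized NSCLC, clinicians need
to know which patients still carry residual disease before radiographic
progression. ctDNA mutation profiling is specific but insensitive at
the low post-treatment tumor fractions. An alternative signal is the
*neomer*: a short DNA sequence (here 16 bp) generated by a recurrent
somatic variant that is present in tumor-derived DNA but absent from
the reference genome on either strand. Because a neomer can be found
by exact string matching in raw FASTQ reads, no alignment or variant
calling is needed, and the per-sample feature profile — the ratio of
neomer-detecting reads over all reads, plus a per-neomer read count
vector — is cheap to compute at any depth.

This package implements the full chain for that analysis:

1. **Catalog** (`neomer_mrd.catalog`): from a recurrent-SNV list,
   enumerate all k-mers spanning each alternate allele, keep those
   absent from the reference genome (forward and reverse complement),
   and remove any attributable to common population variants.
2. **Scan** (`neomer_mrd.scanner`): exact, strand-aware matching of
   FASTQ reads against the catalog; per-sample profiles and a cohort
   feature matrix (ratio + counts per million reads).
3. **Risk model** (`neomer_mrd.risk`): a linear ranking survival SVM
   over comparable survival pairs,

       0.5 ||w||² + γ · mean_(i,j) max(0, 1 − w·(xᵢ − xⱼ)),

   where (i, j) is comparable iff sample i progressed strictly before
   sample j's observed time. Scores are produced per time point under
   leave-one-out cross-validation, and high/low-risk calls anchor the
   cutoff at 90% specificity among non-progressors.
4. **Evaluation** (`neomer_mrd.stats`): confusion-matrix metrics with
   exact binomial (Clopper–Pearson) 95% CIs, Cohen's kappa with a
   bootstrap CI, Kaplan–Meier curves and Cox hazard ratios with Wald
   CIs, the model-OR-mutation combination, any-positive longitudinal
   aggregation, and a paired bootstrap accuracy comparison.
5. **Synthetic study** (`neomer_mrd.simulate`): reference genome,
   variant tables, per-sample reads with tumor alleles spiked in at a
   controlled tumor fraction, and survival outcomes with a controlled
   hazard ratio — so the whole pipeline is testable end to end.

`neomer_mrd.pipeline.run_all` orchestrates the stages from a YAML
config with digest-based caching; the `neomer-mrd` CLI exposes each
stage (`simulate`, `catalog`, `scan`, `fit`, `evaluate`, `run`).
See `docs/methods.md` for models, assumptions and parameter rationale.

## Worked example

The numbered drivers under `analysis/` run the demo study (1 Mb
genome, 200 recurrent SNVs, 40 patients sampled at three time points,
5% tumor fraction in MRD-positive samples, true hazard ratio 4):

```bash
cd analysis
python 01_simulate_cohort.py
python 02_build_catalog.py
python 03_scan_reads.py
python 04_fit_risk_models.py
python 05_evaluate_predictions.py
python 06_replicate_published_metrics.py
python 07_parameter_recovery.py
```

Output of the catalog and scanning stages (seed 0):

```
  200 recurrent SNVs -> 3200 candidate 16-mers -> 3200 reference-absent
  -> 2880 neomers after population filtering
  mean neomer-read ratio: MRD-positive 0.0443 vs MRD-negative 0.0000
```

Each recurrent SNV yields up to 16 candidate windows; on a 1 Mb toy
genome essentially all are reference-absent, and the population filter
removes the 10% of SNVs deliberately duplicated into the population
list (16 windows x 20 shared SNVs = 320 candidates). MRD-positive
samples show the elevated neomer-read ratio the feature is designed
around — about the simulated 5% tumor fraction minus the share of
population-filtered SNVs; MRD-negative samples contain no catalog
sequence at all.

Model fitting and evaluation (seed 0):

```
TP1: 36 LOOCV folds, 22 high-risk calls, achieved specificity 1.000 (target 0.90)
TP1 (n=36): neomer sensitivity 75.9%, specificity 100.0%, HR 3.91, kappa vs mutation 0.438
longitudinal (any time point high): sensitivity 87.5%, specificity 100.0% over 39 patients
```

(Exact numbers for all three time points and methods are written to
`results/demo_metrics.tsv` and `scratch/run/report/report.json`; the
lines above are from the seed-0 run and will differ for other seeds.)
The achieved specificity is always at least the 0.90 target by
construction — here the pooled out-of-fold scores separate so well that
no censored patient is called high-risk at all. The hazard ratio of the
TP1 high-risk calls (3.91) recovers the generator's true value of 4 up
to sampling noise, and OR-combining the model with the (simulated)
mutation assay trades specificity for sensitivity, exactly as the
combination rule must. Sensitivity against *observed progression* sits
well below 100% even though the model separates the true MRD labels
cleanly: progressors whose samples carry no tumor reads (MRD-negative
by construction) cannot be detected by any read-based feature.

`06_replicate_published_metrics.py` re-derives every published
operating-point statistic of the emulated study from its printed
confusion matrices:

```
45 published metrics recomputed; largest point-estimate discrepancy 0.00 percentage points
TP3 model-vs-assay kappa: recomputed 0.2574 (bootstrap 95% CI -0.159-0.689), published 0.2574
```

and `07_parameter_recovery.py` closes the loop on the generator:

```
Cox recovery (true HR 4.0, n=200, 100 replicates): median HR 4.11, Wald 95% CI coverage 94/100
MRD-label recovery (40-patient cohorts, 5% tumor fraction, 20 seeds): median sensitivity 0.93
```

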