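# Methods

This package implements a neomer-based molecular-residual-disease (MRD)
analysis for plasma cfDNA sequencing, together with a fully synthetic
study generator so that every stage is testable without access to
clinical data. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design
was genuinely open.

## Neomer catalog

A *neomer* is a k-mer (default k = 16) that spans the alternate allele
of a recurrent single-nucleotide variant and is absent from the
reference genome. Construction proceeds in three stages:

1. **Enumeration.** For each recurrent SNV, all k windows covering the
   variant position are generated with the alternate base substituted
   (fewer near contig ends). Windows containing non-ACGT characters
   are discarded.
2. **Reference absence.** A candidate survives only if neither it nor
   its reverse complement occurs anywhere in the reference. Absence is
   tested against an exact forward-strand k-mer set; requiring absence
   on both strands is our choice (sequencing reads come from either
   strand, so a sequence present on either strand is not
   tumor-specific). Reference windows containing N are never index
   members, i.e. absence is decided against unambiguous sequence only.
3. **Population filtering.** Candidates identical (either strand) to a
   k-mer generatable from a population variant at or above the
   allele-frequency threshold are removed. The threshold defaults to 0
   — any listed population variant filters — since "common" is
   otherwise a free parameter; it is exposed as `af_threshold`.

Surviving sequences are stored in canonical form (lexicographic minimum
of sequence and reverse complement), deduplicated across source SNVs
(a sequence reachable from two SNVs becomes one catalog entry with two
recorded sources), and ordered lexicographically so catalog files are
byte-reproducible. Provenance counts (candidates, reference-absent,
final; each both raw and deduplicated) are written alongside.
Coordinates are 1-based in files (VCF convention) and 0-based
half-open internally. Multi-allelic and indel records are skipped with
a warning; the catalog is defined over SNVs.

## Read scanning and features

Reads are scanned for exact matches only: a catalog entry matches a
read when either of its orientations occurs as a substring. Matching
is read-level — a read counts once toward the neomer-detecting-read
total no matter how many entries or occurrences it contains, and the
per-neomer count vector records, per entry, the number of reads
containing it. Quality scores are ignored. The per-sample feature
profile is the ratio of neomer-detecting reads over all parsed reads,
plus the per-neomer counts; in the feature matrix the counts are
normalized to counts per million reads so samples of different depth
are comparable (raw counts are preserved in the profile file). An
optional seeded subsample-without-replacement before counting stands in
for coverage down-sampling in a pipeline that never aligns reads.

## Risk model

The per-time-point model is a linear ranking survival SVM. Pair
(i, j) is *comparable* when sample i progressed (event observed) at a
time strictly earlier than sample j's observed time; ties in event time
are excluded. Fitting minimizes

    0.5 ||w||^2 + gamma * mean_(i,j) max(0, 1 - w . (x_i - x_j))

with no intercept — ranking is translation-invariant and the decision
threshold is chosen downstream. gamma defaults to 1.0 with no inner
hyperparameter search. The pair loss is averaged rather than summed so
that gamma's meaning is independent of cohort size — the comparable-pair
count grows quadratically, and under a summed loss the effective
regularization vanishes for any fixed gamma, letting the exact optimum
interpolate the within-risk-group pair ranking through noise count
features and destroying held-out score quality. Averaging also makes
the fit exactly invariant to duplicating every sample. Features are
standardized with training-set mean/SD (constant features get unit
scale).

The optimum is computed through the problem's Lagrange dual, a
box-constrained quadratic program (one multiplier per comparable pair),
solved exactly by cyclic coordinate descent with a primal–dual-gap
convergence certificate. Direct subgradient descent on the nonsmooth
hinge stalls at kinks, which is visible as a duality gap and as
fold-to-fold score noise under LOOCV; the dual route avoids both. For
training sets with more than 4000 comparable pairs — where the pair
Gram matrix becomes large — the implementation falls back to L-BFGS-B
on the primal objective, parametrized in the span of the training rows
when features outnumber samples.

Evaluation is leave-one-out cross-validation: each sample is scored by
a model fitted on the other N − 1 samples, with standardization
recomputed inside each fold, so no information about the held-out
sample reaches its scorer. Folds are identified by sample id, making
scores invariant to input row order.

Binary high/low-risk calls anchor the cutoff at a target specificity
(default 0.90) among non-progressors, on the pooled out-of-fold scores:
the cutoff is the smallest observed score c (or +inf) such that the
fraction of non-progressors scoring below c reaches the target, and a
call is high-risk when score >= c. Censored patients count as
non-progressors — a landmark-analysis simplification that matters when
follow-up is short. Pooled cutoffs are the default because they yield
one confusion matrix per time point; a per-fold training-score cutoff
is available via `cutoff_mode="per_fold"`. By construction the
achieved specificity on the labeling set is never below the target;
when all scores tie, the cutoff is +inf and nobody is called high-risk.

## Evaluation statistics

* Proportions (sensitivity, specificity, PPV, NPV, accuracy) carry
  exact binomial (Clopper–Pearson) 95% CIs via beta quantiles, with the
  lower bound 0 at x = 0 and the upper bound 1 at x = n. Metrics with
  a zero denominator are reported as undefined (null), never 0.
* Cohen's kappa between the model's calls and the ctDNA mutation assay
  uses the standard chance-corrected form; its CI is a percentile
  bootstrap over the n paired calls (default 2000 resamples; resamples
  with degenerate marginals are dropped).
* Hazard ratios come from a univariate Cox proportional-hazards fit on
  the binary high-risk indicator (lifelines, Efron ties), with Wald CI
  exp(beta ± 1.96 se). A monotone partial likelihood (e.g. all events
  in one group) is flagged as unconverged with an infinite-bound CI
  rather than raised. Kaplan–Meier curves are emitted as coordinate
  tables; no plotting dependency in the core.
* The combined predictor is the logical OR of model call and mutation
  status; by construction its sensitivity is at least each component's
  and its specificity at most each component's.
* Longitudinal aggregation is any-positive across a patient's available
  time points (the only rule consistent with aggregation increasing
  sensitivity at some specificity cost), optionally restricted to
  patients sampled at all time points; the aggregated calls default to
  the combined predictor, switchable to neomer-only.
* The longitudinal-vs-single-time-point comparison bootstraps patients
  with replacement (default 1000), computes accuracy per resample for
  each strategy, and applies a two-sided Wilcoxon signed-rank test to
  the paired accuracy vectors.
* p-values are reported but no analysis decision depends on them.

## Synthetic study generator

The generator emulates the full input surface of the emulated study
design on a toy genome: a uniform-random single-contig reference,
recurrent-SNV and population-variant tables, per-sample single-end
FASTQ files, and patient-level survival outcomes.

Fixed by the emulated design: k = 16; a 44-patient cohort sampled at
three time points with 39/33/25 samples; 150-bp reads. Chosen here,
where no value is fixed (the scale is deliberately small enough for
exhaustive testing, and the demo sizes below are this package's own
choices):

| parameter | default | rationale |
| --- | --- | --- |
| genome_length | 1,000,000 bp | large enough that random 16-mers are almost surely reference-absent, small enough for an exact in-memory index |
| n_recurrent_snvs / n_population_variants | 200 / 100 | hundreds-to-thousands of catalog entries, like the real catalog's order of magnitude after scaling |
| reads_per_sample | 2000 | gives ~100 tumor reads per positive sample at 5% tumor fraction — comfortably detectable but not trivial |
| tumor_fraction_positive / negative | 0.05 / 0.0 | post-treatment plasma tumor content is a few percent; negatives carry no tumor reads |
| true_hr | 4.0 | the emulated study's per-time-point hazard ratios cluster near 3.6–4.0 |
| censoring_rate | 0.2 | implied by an emulated ~26-month median follow-up at the default event rates: solving the follow-up calibration at 0.2 puts the central follow-up near two years, and HR-4 patients then censor at ~2% |
| mrd_positive_rate | 0.5 | roughly balanced risk groups, as observed |
| baseline_event_rate | 1/24 per month | median PFS of ~1.4 years for low-risk patients, a plausible scale for inoperable localized NSCLC |
| mutation_assay_sensitivity / specificity | 0.8 / 0.9 | an imperfect binary assay, so the OR combination has something to add |
| overlap_fraction | 0.1 | some recurrent SNVs also appear in the population list, exercising the population filter |

Tumor reads carry exactly one alternate allele; variant positions are
kept >= k apart so each neomer traces to one SNV (k-mer collisions are
covered by a dedicated constructed test instead). Quality strings are
constant. Per-sample read streams use a sub-seed hashed from (global
seed, sample id), so adding samples never perturbs existing ones.

**Survival.** Event times are exponential: rate `baseline_event_rate`
for MRD-negative patients and `true_hr` times that for MRD-positive.
Censoring is administrative: each patient's follow-up ends at an
independent Uniform(0.7 T, 1.3 T) time, with the central follow-up T
calibrated (Brent root-finding on the closed-form censored fraction)
so the marginal censored fraction equals `censoring_rate`. This
follow-up-window law was chosen over censoring uniform on (0, T)
deliberately: a cohort followed for years censors almost no high-hazard
patient, whereas uniform-from-zero censoring truncates many high-risk
patients early, producing censored-yet-MRD-positive patients whose high
scores sit in the non-progressor set and pin the specificity-anchored
cutoff above every true positive — a pattern the emulated prospective
design does not exhibit. Under the follow-up law, HR-4 patients censor
at only a few percent, matching the study's structure. A Weibull shape
is left as a config extension.

**What the generator does not emulate:** cfDNA fragment-length
distributions, sequencing errors, GC bias, paired-end structure,
multi-variant haplotypes, clonal heterogeneity, or any correlation
between tumor fraction and time-to-progression beyond the shared MRD
label. Passing tests therefore show that the pipeline's machinery is
correct and that parameters controlling the simulation are recovered —
not that the assay would achieve these operating points on real plasma.

## Problem sizes used in checks

The parameter-recovery checks run on scaled-down cohorts chosen as this
package's standard experiment sizes: Cox recovery uses 100 replicates
of 200-patient cohorts (survival layer only); MRD-label recovery uses
20 seeded 40-patient single-time-point cohorts on 100-kb genomes with
60 recurrent SNVs and 2000 reads per sample at 5% tumor fraction —
preserving the demo study's read depth and its features-greatly-
outnumber-samples regime, both of which matter for LOOCV score
stability. The
brute-force equivalence checks use toy genomes of a few kb with
k ∈ {4, 8, 16}.

## Numerical and degenerate-input choices

* Cutoffs break ties conservatively: the all-tied-score case yields
  +inf (nobody high-risk, specificity 1).
* A LOOCV fold with no comparable pairs raises an error naming the
  fold; fewer than 3 samples is an error.
* A Cox fit needs both groups non-empty and at least one event;
  separable groups are flagged, not raised.
* Empty catalogs are a warning, not an error; scanning against an
  empty catalog yields ratio 0 and an empty count vector.
* Reports round floats to 8 decimals and contain no timestamps, so
  identical configurations produce byte-identical reports; wall-clock
  timings live only in the run manifest.
* Pipeline stages are cached by SHA-256 content digest of their inputs
  (files plus the relevant configuration slice). A deleted output
  reruns its stage; because regeneration is deterministic, downstream
  stages whose recorded digests still match are recognized as valid and
  skipped.

## Known limitations

* The sSVM is the plain comparable-pair hinge ranking objective; no
  kernel, no regression term, no hyperparameter search. gamma and the
  cutoff mode are exposed but unexplored by default.
* Censored-as-negative labeling biases specificity-anchored cutoffs
  when censored high-risk patients exist; the generator's follow-up
  design makes this rare but real cohorts with short follow-up would
  not be so forgiving.
* The exact k-mer index is an in-memory Python set: appropriate for
  toy genomes up to tens of megabases, not for a full human genome.
* Single-end reads only; paired-end reconciliation and UMI handling are
  out of scope.
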