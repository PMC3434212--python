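# Methods

This note documents the models, parameter choices and numerical decisions
behind beadpipe, and what the synthetic-data experiments do and do not show.

## The synthetic cohort

`simdata.generate_cohort` emulates a two-group monocyte transcriptome study:
12 healthy controls sampled at baseline, 18 patients sampled at baseline,
and the first 12 patients resampled after a short treatment course.  The
gene model is additive on the log2 scale:

    level(g, s) = μ_g + fc_g·[patient] + sig_subj(g)
                + τ_g·[post] + crp_g·[high-CRP patient]

* **Baseline levels μ_g.**  Non-expressed genes and negative-control probes
  sit at the array background, N(7.0, 0.1²) log2 units per probe; expressed
  genes (a fraction `frac_expressed = 0.5` of probes) draw
  U(8.5, 13).  The narrow per-probe background spread keeps the detection
  null approximately exchangeable; a wide spread would make a fixed fraction
  of background probes systematically detectable, which real negative-control
  designs are built to avoid.
* **Differential expression fc_g.**  `n_de_genes = 100` expressed genes get a
  patient-group shift whose log2 value is drawn from N(0, 0.25²) truncated to
  the configured linear range (default 0.3–1.7).  Effects therefore
  concentrate near fold change 1 with the range endpoints as rare extremes —
  the structure of a study whose fold-change-thresholded gene counts collapse
  steeply as the threshold tightens.  A uniform draw over the linear range
  would make more than half the planted effects stronger than 1.35× and is
  not what "low fold changes" looks like.
* **Per-subject signatures.**  Every subject (controls included) carries a
  gene-wise independent signature N(0, patient_effect_sd²) on the expressed
  genes, identical at both timepoints; the default 1.0 log2 units makes
  individual identity the dominant variance component, which is what lets a
  treated sample cluster back to its own baseline.  Patients selected as
  *heterogeneous* (`n_heterogeneous_patients = 4`) receive additional
  N(0, hetero_extra_sd² = 1.0) signature noise.
* **Treatment.**  The post-timepoint shift τ_g ~ N(0, treatment_effect_sd²)
  is shared across treated subjects.  The default sd is 0.02 log2 units —
  an average treatment effect at the detection floor — because the emulated
  design expects a brief treatment course to leave the average transcriptome
  essentially unchanged, with responses dominated by individual variability.
  The exception is the
  contamination pair (red-cell-lineage analogues such as HBB/HBA2, whose
  signal in monocyte preparations tracks reticulocyte carry-over): these two
  expressed genes get a fixed +log2(1.5) post-treatment shift, the one
  robust treatment response the pipeline should recover.
* **CRP.**  Patients draw lognormal CRP levels (median ≈ 4 mg/l, right
  skewed; controls ≈ 1 mg/l).  Optionally, `n_crp_linked_genes` get an extra
  shift only in the highest-CRP third of patients, for tertile-contrast
  experiments.  Off by default.
* **Beads.**  Intensities are 2^(level + N(0, measurement_sd² = 0.5²)) with
  `beads_per_probe = 30`; a fraction `outlier_bead_rate = 0.02` of beads is
  multiplied by ×4 or ×¼ (coin flip) — multiplicative gross errors produce
  the heavy-tailed bead distributions the MAD filter targets.

Randomness derives from one `SeedSequence(rng_seed)` split per consumer
(gene model, qPCR plate, one stream per sample), so output is bit-identical
for a fixed seed and independent of generation order.

**What the generator does not emulate:** probe-level sequence effects and
cross-hybridization, spatial/scanner artifacts, correlated gene modules
(signatures are gene-wise independent), batch effects, and clinical
covariates beyond CRP.  Passing recovery tests on this generator shows the
statistical machinery is correct and calibrated under the study's design —
not that the pipeline is robust to structured artifacts absent from the
model.

## Preprocessing decisions

* **MAD filter.**  Unscaled MAD (no 1.4826 factor), inclusive bounds;
  with MAD = 0 the literal rule retains only beads equal to the median
  (`mad_zero_policy="strict"`, logged; `"retain_all"` available).
* **Detection call.**  ±2·unscaled-MAD trimming is aggressive (it clips a
  clean normal sample at ±1.35σ), and the retained beads concentrate around
  the sample median; the within-probe bead variance therefore understates
  the sampling variance of the trimmed mean by roughly 3×, and a bead-level
  two-sample t-test against pooled negative-control beads calls ~18% of null
  probes present at α = 0.05.  The pipeline instead tests each probe's log2
  trimmed mean against the *distribution of negative-control probe trimmed
  means* on the same array (one-sided predictive t with m−1 df): the control
  summaries are subject to the same trimming, so their spread is the right
  reference, and measured null presence is ≈ 5%.  A bead-level Welch variant
  (`detection_call`) remains available for direct two-sample questions.
  Within one array all probes share the same m = 100 control summaries, so
  per-array presence fractions fluctuate beyond binomial noise; calibration
  statements refer to the mean over arrays.
* **Group activity.**  Presence thresholds 8/12 and 13/18 are lookup values;
  other group sizes use the smallest count whose one-sided Z-test against
  p₀ = 0.5 (no continuity correction) reaches p < 0.05.  No single standard
  rule reproduces both printed thresholds, so the lookup takes precedence
  and the Z-rule is a documented fallback.
* **Missing probes.**  A probe losing all beads on an array is imputed with
  that array's minimum summarized intensity and called absent (logged).

## Differential expression

* **Quantile normalization** is exact rank alignment after log2; ties within
  a sample receive the mean of the reference values their tied ranks span.
* **Regularized t.**  The background variance σ₀² is the mean *pooled*
  variance over the 101 genes nearest in overall mean expression (window
  truncated at the ends).  The pooled sample variance is shrunk as
  s̃² = (c·σ₀² + ν·sp²)/(c + ν) with ν = n₁+n₂−2 and confidence c = 10
  pseudo-observations, and the statistic uses ν + 2c − 2 degrees of freedom.
  Regularizing the pooled variance (rather than each group's separately)
  makes the c → 0 limit *exactly* the ordinary pooled t, which anchors the
  statistic's null behaviour; measured null rejection at p < 0.05 is ≈ 4.8%
  on 5,000 exchangeable genes.  If a window's variance is zero it falls back
  to the smallest positive gene variance (logged).
* **Fold change** is 2^(Δ mean log2) on quantile-normalized values — the
  convention consistent with testing on the log scale.  DE testing is
  restricted to the assessed (group-active) gene set.  No multiple-testing
  correction by default, matching the small-sample design the pipeline
  targets; `add_fdr=True` appends a BH column.
* **CRP tertiles.**  Baseline patients sorted by CRP (ties by sample id);
  lowest and highest ⌊n/3⌋ are each tested against all controls on the
  globally assessed gene set.

## Clustering and heterogeneity

* Ratios are linear-scale signals divided by the per-gene mean over the
  baseline samples ("signal relative to average baseline").
* UPGMA on Euclidean distances; at each merge the subtree containing the
  lexicographically smallest sample id goes left, so the leaf order is
  deterministic and independent of input order.  Self-clustering is scored
  as strict leaf adjacency of a subject's two samples — the strictest
  checkable reading of "clusters next to its own baseline".
* Heterogeneity: per-gene reference is the control mean (leave-self-out for
  controls, to avoid the ~1/m self-bias); a patient is flagged when its
  log2-ratio SD exceeds mean + `flag_k`·sd of the control SDs
  (`flag_k = 2`).  The gene set defaults to all assessed genes
  (config-switchable to DE genes only).  Note the rule's intrinsic false-flag
  rate: a threshold two control-SD units above the control mean is near the
  96th percentile for any sample exchangeable with controls, so with 14
  non-heterogeneous patients roughly a third of cohorts flag at least one
  extra patient even when the planted patients are perfectly separated (they
  are: the planted 4 carry the 4 largest SDs in every tested seed).  Exact
  set recovery is therefore a property of the flag rule, not of the SD
  ranking.

## qPCR validation

* Replicates with quality < 0.65 are dropped; surviving replicates are
  averaged; empty cells are missing and excluded (logged).
* geNorm M: mean over partners of the SD of pairwise log2 ratios,
  pairwise-complete with a 3-shared-sample minimum.
* NormFinder-style stability: per-sample candidate-mean centering removes
  loading; the candidate's intergroup difference is shrunk by its sampling
  variance against the across-candidate spread of differences
  (empirical Bayes), and stability = sqrt((d̃/2)² + intragroup variance /
  mean group size).  Without the shrinkage, a noisy candidate whose
  group-difference estimate happens to cancel the common offset can
  spuriously beat a genuinely stable gene.
* The simulated plate designs one tight reference (0.05 cycles
  sample-to-sample, GAPDH analogue) against three candidates at 0.5–0.6
  cycles; both criteria select it essentially always.  When the two criteria
  disagree on real data the geNorm winner is used and a warning logged —
  disagreement is a data-quality signal.
* ΔΔCt: ΔCt = Ct_target − Ct_reference per sample; ΔΔCt is the group-mean
  difference; fold = 2^−ΔΔCt; group tests on the ΔCt scale (Student, or
  paired for matched timepoints), which is closer to normality than the
  fold-change scale.

## Problem sizes and runtime

Desk-scale defaults (2,000 probes, 100 negative controls, 30 beads/probe)
keep a full cohort simulation-through-qPCR run at a few seconds in memory
and ~15 s with all tab-separated artifacts written; the multi-seed recovery
experiments in the acceptance tests use 20 seeds at these sizes.  All
parameters scale to full-array size (25,528 probes) with linear cost.

## Known limitations

* The regularized-t degrees of freedom (ν + 2c − 2) are a convention, not an
  exact sampling distribution; calibration was verified empirically at the
  default confidence.
* geNorm is implemented as the M statistic for a fixed candidate panel; the
  iterative exclusion procedure for choosing *pairs* of references is out of
  scope.
* The GEO series-matrix shim imports expression tables only (no SOFT
  metadata, no download) and enters the pipeline at the normalization stage;
  bead-level artifacts (IDAT) are not parsed.
* Clustering confidence (bootstrap) and covariate association are not
  implemented.
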