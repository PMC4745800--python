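# Methods

This note documents the statistical model behind `rppamet`, the choices
made where the procedure was genuinely open, and what the synthetic study
conditions do and do not demonstrate.

## Metagene derivation

For one protein with RPPA levels across samples, the low and high strata
are defined by the first and third quartiles, with inclusive boundaries
(value ≤ Q1 → low, ≥ Q3 → high), so ties can enlarge the extreme groups
beyond 25 %. All quantiles in the package — stratification, median
dichotomization, alignment — use linear interpolation between order
statistics (the classical "type 7" definition, numpy's default), stated
here once and applied consistently. Proteins need at least 8 non-missing
values; missing RPPA values are excluded pairwise.

Differential expression between high and low strata uses a two-sample
t-statistic with robust estimators of location and spread. The default is
**Yuen's trimmed-mean Welch t** (20 % trimming, winsorized variance,
Welch–Satterthwaite degrees of freedom). This choice is deliberate: the
superficially natural plug-in of median and 1.4826·MAD into the Welch
formula is anti-conservative under normality — the sampling variance of a
median is π/2 times that of a mean, so the statistic rejects ≈ 12 % of
true nulls at nominal α = 0.05 (n = 50 + 50) — whereas Yuen's test stays at
≈ 5.3 % while still bounding the influence of outliers. The median/MAD
variant remains available (`estimator="median-mad"`) for sensitivity
analyses; the estimator sits behind one function so further alternatives
are pluggable. Degenerate strata (zero robust scale in both groups) yield
t = 0, p = 1 when the locations agree and p = 0 with a logged flag when
they do not, instead of propagating NaNs.

Benjamini–Hochberg adjustment runs **per protein across its genes**; the
metagene is the set with q ≤ 0.05, each member signed by the direction of
its location difference. A protein may legitimately deliver no metagene.
No expression or variance pre-filtering is applied before testing.

## Scoring and external validation

The signature score is the plain signed sum Σ sᵢ·eᵢ over members present in
the dataset, computed on (quantile-aligned) intensities without per-gene
standardization; an optional z-scored variant is not the default because
the plain sum is the quantity the validation gates were designed around.
Members absent from a dataset are skipped and reported as coverage; below
50 % coverage the score is refused rather than silently degraded.

Validation against an independent matched dataset is two-gated:

* **Correlation gate** — signed Pearson r ≥ 0.5 between the score and the
  continuous RPPA level of the source protein, pairwise-complete. The
  signed (not absolute) r is intentional: a correctly oriented metagene
  must correlate positively.
* **Discrimination gate** — Mann–Whitney AUC of the score over the
  validation dataset's **own** quartile-derived low/high strata
  (recomputed there, for symmetry with derivation; intermediate samples
  enter the correlation but not the AUC), with BH across all testable
  metagenes and q ≤ 0.05. The AUC p-value is the two-sided Mann–Whitney
  test (normal approximation, tie-corrected), equivalent to testing
  AUC = 0.5.

Metagenes whose source protein is absent or degenerate in the validation
RPPA are marked untestable and excluded from the BH family.

## Overlap networks and cluster similarity

Intersection significance between gene sets of sizes Na and Nb in a
universe of N genes is the exact hypergeometric upper tail P(X ≥ n),
evaluated through the survival function in log space. Overlaps count the
union of up- and down-members, ignoring signs. The universe defaults to
the genes measured in the derivation matrix and is configurable, since the
correct N is analysis-specific. Network edges require both BH q ≤ 0.05
(across all pairs) and at least 5 shared genes; the minimum-overlap rule
binds even when p is tiny. Node grouping is connected components by
default with an optional seeded label-propagation pass; heavier graph
clustering is out of scope.

Cluster similarity between two views of the same entities is the plain
(unadjusted) Rand index of the partitions obtained by complete-linkage
hierarchical clustering, Euclidean distance, applied to the rows of each
view's Pearson correlation matrix and cut into k = 3 classes.
Zero-variance entities are excluded with a warning.

## Survival screen

Scores are dichotomized at the median (ties fall low). Within each stratum
a Cox proportional-hazards model with the configured covariates estimates
the treated-vs-control hazard ratio; tie handling is Efron's. Interaction
is the Wald p of the arm × score product term in a model containing both
main effects and the covariates, computed twice — with the dichotomous and
with the continuous score. BH across metagenes uses the dichotomous
interaction p; the continuous results are reported alongside. The
covariate list is fully configuration-driven (the package presets none),
and a subgroup option reruns the identical machinery on a clinical subset
(e.g. an ER stratum). Monotone-likelihood or non-convergent fits return a
flagged result with an infinite confidence interval instead of aborting the
screen; a metagene with an empty stratum × arm cell is marked untestable
and excluded from BH.

## Cross-dataset alignment

"Quantile alignment" is implemented as per-dataset multiplicative
rescaling: each matrix is multiplied by one scalar so the 0.95-quantile of
its pooled values matches that of the reference (first) matrix. This is
the simplest operation consistent with a single-quantile normalization of
log-intensity matrices; per-sample or additive variants were considered
and rejected as defaults because they alter within-dataset structure that
the downstream correlation gates depend on. Rescaling leaves correlations,
AUCs and median splits invariant, so alignment matters only where absolute
scores are compared across datasets.

## Synthetic study conditions

The generator plants one latent activation Aₚ ~ N(0,1) per protein and
sample (independent across proteins by default). RPPA readout is
Aₚ + N(0, 0.5). Member genes follow b_g + sᵢ·effect·Aₚ + N(0, 1) with
log-intensity baselines b_g ~ N(8, 2); 30 % of members are planted with
negative coefficients so sign handling is exercised. Defaults: 200
derivation samples, 100 validation samples, 20 proteins of which 10 are
informative with 50-gene metagenes, 1000 genes total, effect size 1.0.
The validation cohort is drawn from the same model and then put on a
different intensity scale (×1.5, +0.5) to exercise alignment.

Survival is exponential: log hazard = log(0.01/month) + arm·log(0.6) +
arm·z·1.25, where z is the standardized true score of the planted
interaction protein. The interaction coefficient 1.25 per SD is anchored
to the benefit contrast reported for the ANXA1-type pattern this screen is
designed to find (stratum hazard ratios near 0.16 vs 1.3 imply a ≈ 2.1
log-HR gap between median strata, ≈ 1.3 per SD); the arm main effect
log(0.6) represents a realistic overall adjuvant benefit. Censoring is an
independent exponential whose hazard is solved numerically so the expected
censored fraction is 30 %. Everything is reproducible bit-for-bit from one
integer seed via spawned generator streams.

What the synthetic conditions do **not** emulate: probe-level microarray
noise, batch effects, correlated latent factors (an option exists but is
off by default), non-proportional hazards, informative censoring, and the
scale of real cohorts. Passing tests therefore demonstrate correctness of
the machinery and its calibration under a clean generative model, not
clinical reproducibility on TCGA-scale data.

## Verification and problem sizes

The test suite checks each formula against an independent implementation:
the score against an explicit member loop, the hypergeometric tail against
exact integer arithmetic over every configuration with N ≤ 25, the Rand
index against pairwise enumeration, and BH against the hand-applied
step-up definition. Calibration experiments use 10,000 null draws for the
robust t (n = 50 + 50), 1,000 null cohorts of n = 200 for the Cox
interaction test, and n = 500 per class for the binormal AUC benchmark.
Recovery experiments run the full pipeline under the default conditions:
100 seeds for member recovery, 25 seeds for cross-cohort validation and
for the screen's top-rank rate, and n = 2,000 for hazard-ratio recovery.
`scripts/acceptance.py` repeats the same measurements at moderately
reduced replicate counts (30/15 seeds, 500 null cohorts, n = 5,000 for the
AUC benchmark) and writes them as JSON.

## Known limitations

* The robust t assumes exchangeable samples within strata; no covariate
  adjustment is available at the derivation stage.
* Stratum hazard ratios from small strata can be unstable; the screen
  reports convergence flags rather than suppressing them.
* The hypergeometric universe is a modelling choice; enrichment q-values
  shift with it.
* GMT descriptions are not preserved through round-trips (only set
  membership is).
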