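# Methods

## Differential-expression selection

Selection is a pure threshold filter on linear RPKM values — no dispersion
model, no p-values — matching the single-replicate design it serves. The
fold change is `(treated + c) / (control + c)` with pseudocount `c = 0.1`.
The pseudocount makes zero-abundance genes well-defined while staying small
against the abundance gates (RPKM > 2 for induced, > 1 for repressed
genes); it pulls all fold changes toward 1, so it can only make selection
more conservative. All inequalities are strict. For repressed genes the
abundance gate applies to the *untreated* value: a gene silenced by
treatment has low treated abundance by construction, so gating on the
treated value would discard exactly the events of interest.

The co-stimulation overlap applies the same up-regulation predicate to
(TGF-β vs control) and (TGF-β+TNF-α vs control) and reports the two-set
partition. Ortholog translation keeps all targets of one-to-many mappings
and collapses many-to-one collisions by set union; counts before/after are
recorded in the run manifest so attrition is auditable.

## Normalization and scores

Quantile normalization here is **gene-wise**: the reference distribution is
the per-rank mean of each gene's sorted value vector across samples, and
each gene's values are replaced by the reference at their within-gene ranks
(ties get the mean of the tied reference values). Afterwards every gene has
the same sorted values, hence identical mean, median and variance; the
transform is idempotent. This is deliberately the transpose of conventional
sample-wise quantile normalization: the goal is to make genes exchangeable
within a score average so that no high-variance gene dominates, not to make
samples comparable.

Scores are differences of means over normalized values: TGF-β and ECM
scores on quantile-normalized log2 expression, the EMT score on per-gene
z-scores (sample SD, denominator n−1; constant genes map to z = 0 rather
than erroring). A difference of means cancels any per-sample additive
shift whenever both components are non-empty, so library-size offsets on
the log scale do not leak into two-sided scores. Signatures with fewer
than 50% of either directional component present raise a coverage error
listing the missing genes — failing loudly beats a silently biased score.
Cohort matrices on linear scale are log2(x+1)-transformed first
(`log2_transform` is configurable off for pre-transformed data; the
raw-value scale of public cohort matrices varies, which is also why the
strata cuts are configurable with defaults 0 and 10).

Ki67 percent positivity maps to the ordinal score via half-open bins
0: =0, 1: (0,1], 2: (1,10], 3: (10,20], 4: (20,30], 5: (30,40], 6: (40,50],
7: (50,75], 8: (75,100] — the only partition of [0,100] consistent with all
the printed bin labels. The binary Ki67 subgroup for the score comparison
is a median split of the ordinal scores by default (cutpoint configurable).

## Survival statistics

Kaplan–Meier uses the product-limit estimator with the standard convention
that a subject censored at an event time is still at risk for that event.
The log-rank test is the unweighted Mantel–Haenszel form:
χ² = (Σ(O₁−E₁))²/ΣV with the hypergeometric variance per distinct event
time, 1 df. Pairwise tests across k strata are Bonferroni-adjusted by the
k(k−1)/2 comparisons actually run, capped at 1. Both are implemented
directly (the conventions above are part of the contract) and are
cross-checked against lifelines in the test suite.

Spearman correlation, Fisher's exact test (two-sided by the
probability-at-most-observed rule), the chi-square test (no Yates
correction by default; flag available) and the asymptotic Mann–Whitney
branch delegate to scipy. Exact small-sample p-values are enumerated in
full: all n! rank permutations for Spearman at n ≤ 8, all C(n, n₁) group
labelings for Mann–Whitney when both groups have ≤ 8 members, both with
average-rank ties. The Ki67 group test defaults to Mann–Whitney (ordinal
staining scores, no distributional assumption) with a Welch-t switch.

## Synthetic generators

The cell-line generator draws log-normal baselines (log2 mean 3, SD 2),
plants induced genes with true fold changes uniform in log2 over 3–8× (TNF
and synergy genes likewise; repressed genes 0.05–0.15×), and adds
independent N(0, 0.25²) log2 noise per condition. Induced/repressed gene
baselines are floored so their true abundances clear the selection gates —
the planted truth is then exactly the set a perfect selector should return,
and the noiseless limit recovers it exactly. Fold-change ranges are kept
clear of the thresholds (lower bound 3 > 2) so recovery failures measure
noise, not boundary effects.

The cohort generator draws a latent activity A ~ N(0,1) per sample and sets
log2 expression of signature genes to baseline + direction·β·A + N(0, σ²)
(defaults β = 1, σ = 0.5; non-signature genes carry noise only). Survival
is exponential with hazard h₀·exp(γ·A) (h₀ = 0.015 events/month, γ = 0.8),
censored at Uniform(0, 120) months — about 45% censoring at the defaults —
and Ki67 percent is 100·logistic(A + N(0, 0.5²)). Cohort size defaults to
108 samples, the size of the study cohort this emulates. One integer seed
drives fixed, independently spawned sub-streams (baselines, fold changes,
noise, survival, Ki67, covariates), so outputs are bit-identical per seed
and enlarging the gene set does not reshuffle the survival draws.

What the generators do **not** emulate: count noise (values are log-normal,
not negative-binomial), gene–gene correlation beyond the single latent
factor, batch structure, informative censoring, covariate–outcome
confounding, and realistic ortholog relations (the synthetic map is an
upper-casing with configurable missing and one-to-many fractions). Passing
recovery tests therefore demonstrate the pipeline's correctness and
calibration under the assumed generative model, not performance on any
particular public dataset.

## Evaluation choices

Calibration and power experiments stratify by empirical score tertiles
(bottom vs top third) rather than the fixed (0, 10) cuts: on an arbitrary
simulation scale fixed cuts can leave strata empty, while tertiles keep
both groups non-empty without changing the null. Null calibration uses
1000 replicates of 120-sample cohorts over a 60-gene universe (50 signature
genes plus filler) — small enough to run in seconds, large enough that the
log-rank chi-square approximation is honest (~30 events per arm); power
uses 200 replicates at n = 200, γ = 0.8.

The packaged EMT/ECM marker GMT is a synthetic stand-in assembled from
canonical marker symbols at the published set sizes (52+25 and 30+28); any
analysis of real cohorts should substitute the original supplementary
lists, which the GMT loader reads unchanged.

## Numerical notes

- Quantile-normalization uses a stable mergesort for rank assignment, so
  equal inputs give identical outputs across platforms.
- Exact-enumeration p-values compare with a 1e-12 slack to avoid
  float-equality artifacts at tied statistics.
- Log-rank variance terms with a risk set of 1 contribute 0 (the n−1
  denominator is guarded); a test with zero total variance reports
  statistic 0, p = 1.
- Score tables round-trip through TSV at 6 decimals (1e-6).

## Known limitations

Single-column conditions only (no replicate handling in selection);
no multivariate survival modelling (the stratified log-rank is the
endpoint); no rank-based (ssGSEA/GSVA) scoring; GMT is the only signature
format; expression matrices must be dense.
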