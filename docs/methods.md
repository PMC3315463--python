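# Methods

## The measurement model

A screen measures one RNA species at a time across thousands of strains.
Each strain contributes two biological replicates (independently grown,
harvested, extracted and reverse-transcribed), each measured in two
technical QPCR replicates, giving four measurements per strain per
target.  A Cp value is related to the starting template quantity through
a log-linear standard curve fitted to a 4-fold dilution series:

    Cp = slope * log10(q) + intercept,    E = 10^(-1/slope) - 1

Quantities recovered by inverting a curve are relative (genomic-DNA-
equivalent nanograms), never absolute copy numbers; all downstream
statistics are ratios, so the unit cancels.  Fitting is ordinary least
squares on log10 quantity; a non-negative fitted slope is rejected as an
invalid dilution series.  Curve fitting uses log10 (slope ≈ −3.32 at
100 % efficiency); every downstream screen statistic uses log2.  The two
bases never mix within a formula.

## Composite normalization

Per-sample RNA yield varies strongly (cell collection, extraction, cDNA
synthesis), and plates differ subtly from run to run.  Six reference RNAs
of diverse function and ~300-fold abundance spread are measured in every
sample.  For sample *i* on plate *p*:

    C_norm(i) = geometric mean over refs r of [ ng_i,r / median_p(ng_r) ]

where the median runs over the CV-passing samples of the same plate.
The geometric mean is a deliberate choice: log2(C_norm) across a screen
is approximately normal (a log-space average is the natural estimator),
and it makes the defining invariance exact — multiplying every
measurement of one sample by any c > 0 multiplies its C_norm by exactly
c and leaves all relative levels unchanged, for every sample on the
plate, because a shift in a plate median rescales all samples' normalized
levels by a common factor that the per-plate Rel median cancels again.
Arithmetic mean and median are available via configuration.

Normalized level = ng / C_norm per technical replicate; relative level
(Rel) = normalized level / per-plate median of normalized levels for the
same target.  By construction the median Rel per plate and target is 1.

Filters, both strict at the boundary:

* **CV filter** — per sample and target, the coefficient of variation of
  the technical replicates on the linear ng scale; values > 0.25 exclude
  the sample for that target, and any failing *reference* target excludes
  the sample entirely.  A CV that cannot be computed (one surviving
  replicate) passes by default (`strict_cv=False` flips this).
* **C_norm filter** — log2(C_norm) < −3 (an 8-fold drop from the plate
  median; very little cDNA) excludes the sample.
* **min_refs = 4** — a composite constant is only computed when at least
  four of the six reference ratios exist, so the composite stays
  composite.

Open granularity choices (the upstream description fixes neither): CV is
computed across the two technical replicates of each biological sample on
the linear quantity scale, and plate medians are taken after CV
exclusions so corrupted wells cannot drag the normalizer.  The total-RNA
target used by the splicing-efficiency index (Tef5 mRNA) is also one of
the six references; relative levels are therefore computed for all
targets, reference or not, and reference-ness only governs C_norm.

## One-class SAM

Input is the strains × 4 matrix of log2 Rel, tested against μ0 = 0 (a
linear-scale option exists).  The moderated statistic is

    d_i = (mean_i - mu0) / (se_i + s0)

with se the standard error of the mean.  At s0 = 0, d is exactly the
one-sample t statistic; s0 > 0 damps strains whose tiny standard errors
would otherwise dominate the ranking.  s0 is chosen from the percentiles
{0, 5, …, 100} of the se distribution by minimizing the coefficient of
variation of windowed median absolute deviations of d across se-quantile
windows (100 windows, fewer for small screens), ties broken toward the
smallest candidate.

The one-class null flips one random sign vector per permutation across
the replicate columns, applied to every strain's deviations from μ0 —
the scheme of the original SAM program, under which the observed data is
itself one of the 2^n permutations.  With n ≤ 12 replicates all 2^n sign
vectors are enumerated exhaustively (16 for the standard four-replicate
design) instead of sampled; sampled nulls converge to the exhaustive one
at the Monte-Carlo rate.  d̄_(i) is the mean over permutations of the
i-th order statistic of the permuted d values.

Calling at threshold Δ: walking up from the smallest nonnegative-d rank,
the first strain with d − d̄ ≥ Δ sets the upper cut; every strain with
d at or above it is called positive (mirror rule for negative).  FDR =
median over permutations of the count of permuted d beyond the cuts,
divided by the number called, capped at 1; no proportion-of-true-nulls
correction is applied by default, matching basic SAM.  A Δ sweep over the
attainable thresholds (the unique values of |d − d̄|, quantile-thinned to
512 points for very large screens) reports calls and FDR per Δ, and the
default operating point is the Δ minimizing FDR subject to at least one
call, ties toward the smallest Δ (most calls).

Strains lacking the full replicate complement are dropped from SAM with
a logged count, not imputed.  Ties in the d ordering break by strain
label for reproducibility.

**Granularity caveat.**  With four replicates the null has only 16
distinct permutations, so FDR estimates are coarse: when very few strains
are called, the median permuted exceedance count is usually 0 and the
estimate collapses to 0 even though some calls may be false.  The test
suite therefore checks FDR behavior on null data in the regime where a
non-trivial number of strains is called, and end-to-end false-call rates
are compared to the reported FDR with an absolute margin.

## Ranks, efficiency, enrichment

Per target, each strain is summarized by the mean of its four log2 Rel
values (symmetric treatment of biological and technical replicates,
matching the SAM input) and ranked descending, average ranks on ties.
The composite rank is the mean of the per-target ranks over the
configured precursor panel; strains with fewer than `min_targets = 3`
ranked targets are flagged and placed last.  The splicing-efficiency
index is relative precursor over relative total RNA for the same
transcript — it rises when splicing, not transcription, is impaired, and
inherits Rel's yield invariance.

Gene-set enrichment among the top-N candidates uses the one-sided
over-representation tail of the exact hypergeometric distribution,

    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n)

evaluated via log-gamma with a suffix log-sum-exp, exact down to
~1e-300.  The background N defaults to the strains passing all filters
for the dataset, not the full library.  When several sets are tested a
Bonferroni-adjusted p is reported alongside, but the raw p is primary.
Candidate reports join per-target SAM calls, order strains by decreasing
maximal d across targets, and evaluate enrichment at top-50/100/200 by
default.

## The synthetic-screen generator

The generator encodes the study conditions it emulates: ~5500 strains
(desk-scale runs use fewer), 2 biological × 2 technical replicates, six
references log-spaced over ~300-fold with the assay baselines expressed
relative to the least-abundant transcript, per-sample yields
2^N(0, sqrt(1.5)) (log2 variance 1.5), per-plate batch offsets
2^N(0, 0.25) (no published magnitude exists; 0.25 log2 is this package's
choice of a "subtle" plate effect), multiplicative log-normal technical
noise with CV 0.05 (mean-corrected so E[noise] = 1), and 1 % dropout.
True quantities are pushed through per-target standard curves (slopes
cycling through the 86–97 % efficiency band, intercept 24 cycles so Cp
stays positive across the abundance range) to produce Cp tables, and the
per-strain effects, per-sample yields and per-plate offsets are persisted
as ground truth with the generating seed.

Spiked strains receive a +2 log2 effect (configurable, or a uniform
range) on precursor targets only — a pure splicing defect; the
`transcription` spike mode raises precursor and total together so tests
can verify that the efficiency index discriminates the two.  Strain
layout is row-major and deterministic from the seed.

What the generator does *not* model: growth kinetics, structured
liquid-handling errors, RNA degradation chemistry, primer-specific
amplification artifacts, or correlated (non-independent) dropout.
Passing parameter-recovery tests therefore demonstrates the pipeline's
correctness under multiplicative log-normal noise with plate structure,
not robustness to every pathology of real instrument data.

## Numerical choices

* Filters use strict inequalities, so boundary values (CV = 0.25,
  log2 C_norm = −3) pass.
* Medians of even-sized groups use the midpoint of the two central
  values.
* All ratios and Rel values are stored on the linear scale; log2 happens
  at the significance and reporting stages.
* Floats are written with 17 significant digits and read back with the
  correctly rounded parser, so write → read → write is byte-identical.
* Degenerate inputs: single-quantity dilution series, non-negative curve
  slopes, zero replicate means, zero reference differences (ChIP), and
  inconsistent enrichment counts all raise descriptive errors; an
  all-zero-se SAM input falls back to the smallest positive fudge factor
  with a warning.

## Problem sizes

Tests and the acceptance script run the full pipeline at desk scale:
2000-strain screens (ten seeds) for spike recovery, 2500 strains × 2
replicates (5000 samples) for yield-variance recovery, 300–500 strains
for end-to-end behavior, and exhaustive oracle checks up to N = 60 for
the hypergeometric tail.  These sizes are the package's own choice of a
fast, statistically informative regime; the pipeline itself handles the
full ~5500-strain design identically.

## Known limitations

* The published per-transcript SAM operating points and significant-
  strain counts of the real screen depend on the deposited data
  (GEO GSE34330) and are not reproducible from synthetic inputs; optional
  integration tests run when those tables are supplied locally under
  `data/GSE34330/`.
* FDR estimates are granular at four replicates (16 permutations); see
  the caveat above.
* The enrichment module tests user-supplied gene sets only; no ontology
  DAG traversal or ontology-wide multiple-testing correction is
  performed.
* ChIP-QPCR support is limited to percent-input fold-enrichment
  arithmetic over an intronless control region.
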