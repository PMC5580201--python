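# Methods

## The model and the procedure

The pipeline treats a biallelic genotyping array as a quantitative
instrument.  Each marker × sample cell carries two non-negative
fluorescence intensities (A, B), one per allele; only their total
T = A + B is analysed.  Normalization expresses each sample's total at a
marker relative to the cohort: x = log2(T / M), with M the across-sample
median of T at that marker.  M is computed over all samples, cases and
controls pooled — a per-marker location reference, not a group contrast —
and for even sample counts it is the arithmetic mean of the two central
order statistics.  Cells with T = 0, and whole markers with M = 0, are
masked rather than floored: any pseudo-count would bias the log ratio by
an amount that depends on the (arbitrary) intensity units.

The scan is gene-windowed.  A marker belongs to every gene whose
[start, end] interval (1-based, inclusive on both ends) contains its
position; overlapping genes share markers.  Genes with ≥ `min_snps`
markers (default 15) are eligible — the threshold trades spatial
resolution for test stability, since the group vectors grow linearly with
marker count.  For each eligible gene the case vector and control vector
concatenate the unmasked normalized values over (marker, sample) cells.
The two vectors are compared by an F-test of variance equality (two-sided,
p = 2·min(Pr(F ≤ f), Pr(F ≥ f)) capped at 1, with f = s²_case/s²_control)
and by Welch's unequal-variance t-test.  Welch rather than a pooled t:
variance equality is tested separately, and conditioning the mean test on
the variance test's outcome would entangle the two families.

Benjamini–Hochberg step-up correction is applied within each family (mean
p-values and variance p-values separately, m = number of tested genes in
both cases).  The headline significant set is the mean-test family.

Covariance PCA summarizes differentiation.  The genome-wide view uses a
samples × genes matrix whose (j, g) cell is sample j's mean normalized
value over gene g's markers; features are centered, the covariance matrix
is eigen-decomposed (via SVD of the centered matrix), and the component
sign is fixed so the case group's mean score is non-negative — a pure
convention that makes plots and regression on scores reproducible.  The
per-gene view applies the same decomposition to one gene's samples ×
markers matrix and reports PC1 scores rescaled to unit maximum magnitude.

## Synthetic data

The generator emulates the target study design: two groups (default 6 vs
6), non-overlapping gene intervals laid round-robin across chromosomes
(default 5), marker counts per gene drawn uniformly from
`snps_per_gene_range` at a fixed 100-bp spacing, plus a block of
intergenic markers after each gene (default 5 per gene) so that flanking
and random-region controls have something to grab.

Per marker s and sample j the total log2 intensity is

    t_js = baseline_s + shift_js + sd_js · z_js,   z_js ~ N(0, 1)

with baseline_s ~ N(10, 0.5²) (a realistic between-probe spread on the
log2 fluorescence scale; the exact values are irrelevant because the
baseline cancels in log2(T/M)), sd_js = `sample_noise_sd` (default 0.3
log2 units), and shift_js = `mean_shift_delta` (default 1.0) exactly when
marker s lies in an effect gene and j is a case sample;
`variance_inflation` (default 1.0) multiplies the case-group sd in effect
genes.  A fraction `effect_gene_fraction` (default 0.10) of genes is
drawn as effect genes.  T = 2^t is split into A and B by a uniform(0.05,
0.95) share, arranged so that A + B reconstructs T bit-for-bit (the
larger share is ≥ T/2, making the complementary subtraction exact in
floating point).  Effects are planted on T, not on the A/B split, because
the analysis only ever sees T.  One `numpy.random.default_rng(seed)`
stream drives all draws in a fixed order (marker counts, effect-gene
choice, baselines, noise, split), so a seed fully determines the dataset.

What the generator does *not* model: genotype cluster structure (the
three-cloud AA/AB/BB geometry), B-allele-frequency information, probe GC
waves, batch or plate effects, and spatial correlation of noise along the
chromosome.  Consequently, passing tests establish the pipeline's
behaviour under an idealized log-normal intensity model with independent
noise — they say nothing about robustness to array artefacts, and
real-data FDR can be worse than the numbers below whenever those
artefacts correlate with group labels.

`evaluate_recovery` scores a scan against the planted truth: FDR =
FP/max(1, FP+TP) and power = TP / (planted ∩ eligible).  Planted genes
that fall below the marker-count threshold are excluded from the power
denominator — they are not recoverable by design — while an *eligible*
planted gene missing from the results raises a consistency error.

## Operating characteristics, and a known miscalibration

`snpscan.experiments.fdr_experiment` (used by `scripts/acceptance.py` and
the acceptance tests) runs independent full-pipeline replicates at the
default conditions: 1000 eligible genes of 15–20 markers, 6 vs 6 samples,
10% effect genes at mean shift 1.0, noise sd 0.3.  Per-replicate seeds
are derived as (base_seed·100003 + r) mod 2³¹.  At these conditions power
is essentially 1.0 and PC1 of the significant-gene matrix separates the
groups in every replicate.

The realized FDR, however, sits slightly **above** the nominal level: the
replicate-averaged value is ≈ 0.05–0.06 (e.g. 0.0581 over the 50
replicates at base seed 1), where BH with 90% true nulls would promise
≤ 0.045 for independent, well-calibrated p-values.  The cause is
structural, not numerical.  Median centering couples the samples at each
marker: writing e for the noise and m for the median of the cohort's 12
noise values, each observation is e − m, whose marginal variance is
σ²(1 + v − 2c) ≈ 0.966·σ² (v = Var(m)/σ² ≈ π/2N, c = Cov(e, m)/σ² ≈ 1/N,
N = 12), while the case−control mean difference — from which m cancels
exactly — keeps variance σ² per observation.  The Welch denominator
therefore underestimates the standard error by ~1.7%, which inflates
far-tail p-values by ~15–25% at the BH effective threshold.  The scan
deliberately treats within-gene observations as exchangeable and applies
textbook two-sample tests to the centered values — reproducing the
procedure as practised rather than correcting it — so this mild
anticonservativeness is an intrinsic property of the method at small N,
and the strict property "mean FDR ≤ 0.05 + 2 Monte-Carlo standard errors"
can fail by a small margin (the corresponding acceptance test documents
exactly this).  Users who need strict FDR control at N ≈ 12 should widen
α's interpretation accordingly or aggregate to per-gene summaries before
testing.

## Numerical choices

- F and t p-values are computed through scipy's regularized incomplete
  beta / Student-t distribution functions, each tail in its
  well-conditioned form; agreement with `scipy.stats.ttest_ind` and with
  quadrature of the F density is verified in tests to 1e-10.
- P-values are clamped to [tiny, 1]; the clamp is reachable only when one
  group variance is exactly 0 (continuous data never hits it).  Both
  variances zero is an undefined test: the gene goes to the skip log.
- BH ties are broken by the stable order of the sorted sequence; flags are
  returned in input order.
- PCA uses SVD of the centered matrix (never forming the covariance
  matrix), eigenvalues s²/(n−1); a constant matrix yields zero scores and
  eigenvalues rather than an error.  Sign convention: case-group mean
  score ≥ 0, falling back to a positive largest-magnitude loading when no
  groups are given or the case mean is exactly 0.
- Region length is end − start; marker containment in regions and genes is
  inclusive of both endpoints; two regions overlap iff max(starts) <
  min(ends), so touching intervals do not overlap.
- Pathway coverage percentages are truncated (floored), not rounded, at
  two decimals, using integer arithmetic so the truncation is exact.
- Chromosome labels are opaque strings ordered naturally (chr2 < chr10)
  for output only.
- Intensity TSVs are written with 17 significant digits and parsed with
  numpy's correctly-rounded float parser, so a write → read round trip is
  bit-exact and simulate-mode and analysis-mode pipeline runs produce
  identical results.

## Problem sizes

The default experiment sizes — 1000 genes × ~22 markers ≈ 22,500 markers ×
12 samples per replicate, 50 replicates — were chosen so a full replicated
experiment completes in well under a minute on a single core while keeping
the Monte-Carlo standard error of the FDR estimate near 0.003.  All unit
and property tests run on datasets of 20–300 genes.

## Limitations

- The two-sample tests ignore correlation among a gene's markers (linkage
  disequilibrium in real data); the synthetic generator's independent
  noise is the friendliest case for this assumption.
- The F-test is highly non-robust to non-normality; it is provided as part
  of the procedure, and its family is corrected separately, but its
  calibration on real intensity data is not established here.
- Haplotype group-consistency uses the strictest definition (a pattern in
  every member of one group and no member of the other); frequency-based
  notions of association are out of scope, as are CNV calling and
  haplotype phasing themselves — the package only filters and compares
  supplied calls and phased strings.
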