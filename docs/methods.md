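# Methods

This note documents the statistical models implemented in `medipdmr`, the
generative model behind its synthetic cohorts, the numerical choices made
where the design was genuinely open, and the limits of what the synthetic
studies demonstrate.

## Measurement model and normalization

A MeDIP two-colour array measures, per probe, a bound (immunoprecipitated,
Cy5) and an input (total DNA, Cy3) intensity. The analysis works on
normalized log2(bound/input) ratios produced by:

1. **Background subtraction** per channel: a per-spot background column is
   used when the intensity table provides one (feature-extraction software
   normally reports it); otherwise the channel's 1st percentile serves as
   a global background estimate. Values are floored at ε = 1 intensity
   unit before the log, so negative or zero intensities never produce
   non-finite ratios. Negative raw intensities are retained at parse time
   and flagged in QC rather than clipped.
2. **Quantile normalization** of the log-ratios across all arrays: every
   array's order statistics are replaced by the across-array mean order
   statistic; tied values receive the mean of their tied positions'
   quantile values, which makes the map deterministic and (on tie-free
   data) idempotent to machine precision.
3. **Replicate averaging**: each subject's replicate arrays are averaged
   with equal weights. The combination rule is symmetric, so it is
   invariant to replicate order. QC (median M, M-vs-A slope, replicate
   correlation) warns by default and excludes arrays only under strict
   mode, because visual-style QC has no defensible automatic exclusion
   rule. Whether to quantile-normalize within replicate pairs instead of
   across the full array set is exposed as a choice; the default
   normalizes jointly.

## Two-level differential methylation

**Probe level.** For each probe, the group difference of per-subject
ratios (log2FC, CPA − NPA) is scaled by an empirical-Bayes moderated
standard error. The prior (d₀, s₀²) is fitted by moment matching on
z = log s²_g using the exact sampling moments of log chi-square variables
(digamma/trigamma), with a Newton inversion of the trigamma function.
When the spread of z does not exceed its sampling expectation, d₀ = ∞ and
s₀² is the mean variance; the moderated t then becomes a z-statistic. At
the other limit, d₀ → 0 recovers the classical pooled two-sample t
exactly. Probe p-values are two-sided from the t distribution with
d₀ + d_g df and are deliberately left uncorrected: they act only inside
the promoter-level call rule.

**Promoter level.** Each promoter's probe t̃ values are compared against
all other probes on the array with a Wilcoxon rank-sum test, computed in
both one-sided directions; the reported p is 2·min(p⁺, p⁻) capped at 1
and the direction is the smaller side. For promoters with ≤ 8 probes on
arrays with ≤ 25 probes total, the tail is computed exactly by a
subset-sum dynamic program over doubled (integer) average ranks;
otherwise a normal approximation with tie and continuity correction is
used (checked against enumeration to ~0.02 absolute). Promoters with
fewer than 3 scored probes are reported untested rather than forced
through a meaningless rank-sum. FDR across tested promoters is
Benjamini–Hochberg (the field default; the step-up rule is tested against
a brute-force implementation of its definition).

**Call rule.** A promoter is called differentially methylated iff
q ≤ 0.05 and at least one of its probes has p ≤ 0.05 and |log2FC| ≥ 0.25.
We additionally require the qualifying probe's sign to match the promoter
direction (switchable off); a sign-discordant "qualifying" probe is
evidence against, not for, the promoter call. The comparison population
for the rank-sum is all non-promoter probes on the array, and log2FC is
computed on replicate-merged per-subject values; both choices are
documented here because alternatives (background restricted to uncalled
regions; per-array fold changes) are equally consistent with the
procedure's usual description.

For the heatmap view, one probe per called gene is selected — the probe
with the most extreme |t̃|, ties broken toward the smaller genomic start
coordinate — and rows/columns are clustered with Ward's minimum-variance
linkage on Pearson-correlation distance (d = 1 − r), verified against a
greedy Lance–Williams oracle.

## Methylation deconvolution

Absolute promoter methylation is estimated from cohort-averaged ratios
with a transparent grid posterior: r_j ~ Normal(a·m·w_j + b, σ²), where
w_j is the probe's CpG-coupling weight — its CpG count plus that of
neighbouring probes within the coupling distance (default 200 bp,
approximating the fragment reach of the immunoprecipitation), normalized
to the promoter maximum. The gain a, offset b and noise σ are estimated
globally by regressing probe ratios on coupling weight in weight bins;
because enrichment identifies only a·m̄, the cohort mean methylation is a
configured constant (default 0.5) that converts slope to gain. The
posterior over m on a uniform [0, 1] grid (step 0.01) yields a mean and
SD per promoter; promoters with no CpG-bearing probe in coupling reach
are reported absent with a reason. This is a sanity-check estimator, not
a fragment-resolution deconvolution: it ignores fragment-length profiles
and CpG-level heterogeneity within the promoter, and its absolute scale
is only as good as the assumed cohort mean. The accompanying expression
check bins genes into twenty 5%-wide expression-percentile bins and
reports per-bin methylation summaries plus a global Spearman correlation
(chosen over Pearson because the expression axis is percentile-framed).

## Genomic organization

**Normalized CpG density** of a region is the observed CpG dinucleotide
density divided by the product of C and G mononucleotide densities
(mononucleotide denominator L, dinucleotide denominator L − 1). Regions
lacking C or G entirely have undefined density and are excluded with a
log record. Hyper- vs hypomethylated call sets are compared with a
two-sided Mann–Whitney U — density ratios are not plausibly normal.

**Distance-correlation curve.** Probe-level group differences Δ are
paired across all same-chromosome probe pairs whose separation falls in a
distance bin (default 8 bins: 0, 50 kb, then log-spaced to 4 Mb — wide
enough that each bin's estimate rests on many effectively independent
pairs). Pairs are uniformly subsampled to a cap (default 200,000/bin) for
tractability. Pearson r is computed over the orientation-symmetrized pair
set; the 95% CI comes from 1000 bootstrap resamples of pairs, and the
null band from 500 within-chromosome permutations of the Δ-to-coordinate
assignment, pooling permuted r values and taking the central 95%. The
**decorrelation length** is the upper edge of the largest-distance bin
such that every estimated bin at or below it has its bootstrap CI
disjoint from the null band (0 if none). Bins with under 30 pairs report
no estimate. Both resampling layers run on pooled sufficient statistics,
so fixed seeds give byte-identical curves.

## Pooled bisulfite-array arm

Beta tables measured on pooled DNA (three pools per group) pass two
probe filters: any CpG whose detection p exceeds 0.001 in **any** pool is
dropped (with three pools a single unreliable value cripples the test, so
whole-CpG removal is the defensible granularity), and any CpG with an
annotated SNP within 10 bp (inclusive boundary) is dropped. Group
differences are tested per CpG with Welch's t on M-values
(logit2 of beta, clipped to [0.01, 0.99] to avoid infinities), BH FDR at
0.05; Δβ is reported on the raw beta scale. Degenerate zero-variance
CpGs are flagged: equal group means give p = 1, different means are the
noiseless-limit boundary p = 0. With three pools per group the Welch df
is 2–4, so this test is deliberately conservative — at the default
simulation noise most planted effects sit just above q = 0.05. Promoter
mapping declares a promoter a hit when at least one significant CpG lies
inside its −1000..+200 window; the tiling design's windows, not an
external annotation, define membership, keeping both platforms on one
coordinate system.

## Overlap and cohort statistics

Set overlaps are tested with the exact upper hypergeometric tail
(identical to one-sided Fisher on the induced 2×2, asserted over random
configurations); the universe for gene-level overlaps defaults to the
design's gene count. The 2×2 Fisher test is two-sided by the standard
"sum of tables no more probable than observed" rule with 1e-7 relative
tie tolerance; degenerate margins return p = 1 with a flag. Two-sample
t-tests accept raw vectors or printed (mean, SD, n) summaries and
implement both pooled and Welch variants, because published tables often
leave the variant ambiguous. Published cohort statistics reproduce to
the extent their inputs allow: the criminal-record Fisher entry
reproduces exactly, while t rows recomputed from rounded summaries land
near, not on, their printed values, as expected from SD rounding.

## Synthetic cohorts

The generator lays out one chromosome with TSSs spaced uniformly at
30–150 kb and 12 probes of 60 bp per promoter at 100 bp spacing across
each −1000..+200 window (every probe fully inside its window). Promoter
sequences are generated at class-dependent GC content (0.40/0.50/0.60)
with CpG observed/expected targets of 0.2/0.5/1.0 via CG knock-out,
spanning the depleted-to-island range of real promoters; probe and window
CpG/C/G counts are taken from these sequences, so the density statistics
run on real counts rather than labels.

Group structure has two layers:

* **Callable effects**: a Binomial(n, π) number of promoters (default
  π = 0.02) receive a ±δ methylation shift in the CPA group
  (default δ = 0.3), with direction hypomethylated at the configured bias
  (default 0.82). Placement follows an exponential kernel around cluster
  centers (scale L = 1.5 Mb); the density link draws hypermethylated
  effects preferentially from CpG-dense promoters and hypomethylated
  effects from CpG-poor ones, the two-sided association needed for the
  called sets to show a density contrast despite MeDIP's blindness to
  CpG-poor promoters.
* **A sub-threshold correlation field**: cluster centers tiled at ~L
  spacing carry symmetric random signs, and every promoter receives a
  group shift of amplitude·tanh(6·Σ signed kernels) — a saturated ±0.022
  methylation field that flips sign on the L scale. This field is what
  gives probe-pair group differences their megabase-range correlation;
  saturation bounds the per-promoter shift so the field alone never
  survives the BH-controlled call rule, and symmetric signs put all of
  its variance into the correlation rather than a constant offset.

Enrichment follows the measurement chain in reverse: per probe,
r = a·m·w + b (defaults a = 2, b = −1) with the same CpG-coupling weight
w the deconvolution uses — coupling the generator and estimator through
one physical quantity is what makes noiseless deconvolution exact to the
grid. Arrays add a per-probe affinity offset (SD 0.15), a per-array
offset (SD 0.10), replicate noise (SD 0.45), a log-normal input channel
(log2 SD 0.5, around 1024 units) and an additive scanner background
(50 units) reported in background columns. Subject-level biological
methylation noise is small (SD 0.01): because it shifts all of a
promoter's probes together, it violates the rank-sum test's
exchangeable-probe assumption, and larger values push the promoter
test's empirical FDR far beyond nominal. The noise split was calibrated
so that the analysis at the study's 5-vs-14 design has controlled
empirical FDR (≤ 0.10 pooled over seeds) with high but not saturated
sensitivity; at this level replicate correlations are ~0.4, so the QC
default (flag below 0.8) marks synthetic arrays liberally — flags warn,
they do not exclude.

Pooled beta tables place 2 CpGs per promoter window; pool betas are
group-level methylation plus Gaussian noise (SD 0.03) clipped to [0, 1],
with 2% of CpGs given a failing detection p in one pool and 5% a SNP
within 10 bp, to exercise the filters.

**What the synthetic studies do and do not show.** They demonstrate that
the pipeline recovers what it is designed to recover under its own
assumptions — planted direction bias, density asymmetry, cluster scale,
calibrated null behaviour. They do not model dye swaps, batch or plate
effects, copy-number variation, cell-composition differences, probe
cross-hybridization, or realistic between-subject methylation
heterogeneity; real-data performance therefore depends on upstream QC
that this package only partially automates.

## Problem sizes and determinism

Calibration and recovery studies run at 2,000 genes (24,000 probes,
~180 Mb) with three fixed seeds — large enough for stable promoter-level
calibration and for the distance curve to resolve the megabase scale,
small enough for a desk machine; distance curves in those studies cap
pairs at 100,000/bin. Full-size runs (20,318 genes) are a configuration
change. All randomness flows from explicit seeds through
`numpy.random.Generator` substreams (one per generator stage), so every
artifact, curve and manifest is byte-reproducible; no global RNG state is
touched.

## Known limitations

* The rank-sum promoter test treats probes as exchangeable; correlated
  within-promoter noise (shared biological or technical variation)
  inflates its significance. The calibration here controls this by
  construction; real data offer no such guarantee, and the residual
  anticonservatism is visible in this package's own recovery studies
  (empirical FDR near, not far below, the nominal level).
* The deconvolution's absolute scale rests on an assumed cohort mean
  methylation; only relative orderings should be interpreted.
* The pooled-arm test is honest but weak at three pools per group; its
  role is validation of direction and effect size, not discovery.
* Printed-table t statistics using rounded summary inputs reproduce only
  approximately; this is a property of the inputs, not the test.
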