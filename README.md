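# medipdmr

Differential promoter methylation from MeDIP tiling arrays, for
small case–control cohorts.

MeDIP-chip profiles genome-wide DNA methylation by immunoprecipitating
methylated fragments with an anti-5-methylcytosine antibody and hybridizing
the bound and input fractions to a two-colour promoter tiling array
(probes every 100 bp across TSS −1000..+200 windows). `medipdmr`
implements the full analysis chain for comparing two groups of subjects on
such arrays — e.g. women on a chronic physical-aggression (CPA) trajectory
versus controls (NPA), profiled in peripheral T cells — together with a
seeded synthetic-cohort generator that makes every stage testable without
any external data.

## The statistical core

Probe level — an empirical-Bayes **moderated t-statistic**. Per-probe
pooled residual variances s²_g (d_g df) are shrunk toward a scaled-F prior
(d₀, s₀²) fitted by moment matching on log s²_g:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)
    t̃_g  = log2FC_g / (s̃_g · √(1/n₁ + 1/n₂)),   df = d₀ + d_g

Promoter level — a **Wilcoxon rank-sum enrichment test** of each
promoter's probe t̃ values against all other probes on the array, one-sided
in both directions (exact enumeration for small problems, tie- and
continuity-corrected normal approximation otherwise), with
Benjamini–Hochberg FDR across promoters. A promoter is called
differentially methylated when its FDR q ≤ 0.05 **and** it contains a
probe with uncorrected p ≤ 0.05 and |log2FC| ≥ 0.25 whose sign matches the
promoter direction.

Around this core the package provides:

* two-channel normalization (background subtraction, log2 bound/input,
  quantile normalization, replicate averaging) with MvA-style QC;
* grid-posterior **deconvolution** of absolute promoter methylation from
  CpG-coupled enrichment, and the methylation-vs-expression sanity check;
* genomic-organization statistics: observed/expected **CpG density** of
  hyper- vs hypomethylated calls (Mann–Whitney), and the
  **distance-correlation curve** of probe-level group differences with
  1000-bootstrap CIs against a 500-permutation coordinate null, from which
  a decorrelation length is read off;
* a pooled bisulfite-array (450K-style) validation arm: detection-p and
  SNP-proximity probe filters, Welch t on M-values with BH FDR, Δβ, and
  promoter mapping;
* overlap statistics (exact hypergeometric/Fisher enrichment, 2×2 Fisher,
  two-sample t from raw data or printed summaries, fold-change
  concordance) for cross-cohort and cross-platform comparisons;
* a synthetic-cohort generator producing the whole input bundle (design,
  two-channel intensities, sample sheet, pooled beta tables, CpG manifest,
  truth set) with configurable effect fraction, direction bias,
  CpG-density linkage and megabase-scale spatial clustering.

## Worked example

Simulate a 2,000-gene cohort emulating the study design (5 CPA vs 14 NPA
subjects, two replicate arrays each, three 450K pools per group) and run
every stage:

```bash
medipdmr --log-level WARNING demo --out demo/ --seed 1 --n-genes 2000
```

prints

```
called 50 promoters ({'hyper': 13, 'hypo': 37})
results in demo/results
```

and `demo/results/manifest.json` records, per stage (abridged):

```
dmr          n_called: 50, direction_counts: {hyper: 13, hypo: 37}
organization density_test: median_hyper 0.797, median_hypo 0.317, p 0.0013
             decorrelation_length_bp: 2138898
beta450k     n_kept: 3723 of 4000 CpGs, n_promoter_hits: 12
```

Reading these numbers: 50 of 2,000 promoters pass the combined call rule,
with the expected excess of hypomethylated-in-CPA calls (the generator
plants an 82% hypo bias); hypermethylated calls sit in CpG-dense promoters
(normalized CpG density 0.80 vs 0.32, Mann–Whitney p ≈ 1e-3); and group
differences at nearby promoters stay correlated above the permutation null
out to ~2 Mb, matching the ~1.5 Mb clustering scale the simulation
injects. Individual stages are available as `medipdmr simulate`,
`normalize`, `run`, `overlap`, `cohort-stats`, `concordance`, and
`design validate`; the same functionality is importable from the
`medipdmr` package.

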