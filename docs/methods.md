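# Methods

## Allele orientation and data model

All tables orient alleles at parse time: `area_risk`/`area_nonrisk` always
refer to the GWAS risk and non-risk allele of the SNP panel entry, so
"R-ratio above the upper cutoff" always means relative loss of the risk
allele.  Tables are UTF-8 TSV with a header row and `#` comments; missing
clinical fields are empty cells, never sentinel numbers.  The readers
enforce every domain invariant (non-negative areas, unique
(sample, SNP, tissue) keys, MAF in [0, 0.5], losses ≤ heterozygotes), so
accepted tables are valid by construction.

## Genotype calling and QC

The genotyping vendor's het/hom decision rule is proprietary, so the caller
is defined here explicitly with two parameters:

* **detection floor** (`genotype.floor_fraction`, default 0.05): an assay
  fails when its total peak area falls below 5% of the cohort-median
  non-zero total.  A failed assay carries both areas as zero.
* **het band** (`genotype.het_band`, default 0.15): a measurement is
  heterozygous when each allele carries at least 15% of the total signal,
  otherwise homozygous for the majority allele.  The band is chosen so the
  smallest standard mixture (20% minor allele) calls heterozygous with
  margin; it is the only knob standing in for the vendor's "aggressive
  call" filtering, which cannot be operationalized further from the
  available description.

Per-SNP failure rates are pooled over both tissues; a SNP is excluded when
its rate exceeds 15% (`qc.max_failure_rate`, boundary retains, mirroring a
strict "greater than" exclusion).  The panel screen keeps SNPs with MAF
strictly above 20% (`panel.maf_floor`) or carrying an explicit low-MAF
exception flag.

A normal/tumor pair is informative when the normal is heterozygous and the
tumor assay succeeded.  When the normal failed but the tumor is
heterozygous, the pair is kept and the normal ratio is imputed as the ratio
of per-allele arithmetic mean areas over all heterozygous normals at that
SNP ("average of the two normal alleles", read literally as means per
allele then the ratio of means; a geometric-mean reading would differ
slightly under noise but has no qualitative effect).

## R-ratio scoring and imbalance calls

R = (normal risk/non-risk ratio) / (tumor risk/non-risk ratio).  Calls use
strict cutoffs: R > upper → loss of risk allele, R < lower → loss of
non-risk allele, otherwise no imbalance.  Two dialects ship:
`standard` (1.5, 0.67 — the quantitative-genotyping convention, default) and
`published` (1.67, 0.60 — the chromatogram-study convention).  The lower
default is the literal 0.67, not 2/3: calls with R in (0.6667, 0.67)
deliberately differ between the two readings, and the asymmetry of the
printed pair is preserved.  R-ratios keep full floating precision; rounding
happens only when reports are rendered.

A tumor allele peak of exactly 0 yields an R sentinel of +inf (risk peak
absent) or 0 (non-risk peak absent).  Such pairs are **counted** as
complete losses in the per-SNP tables but excluded from plot-ready value
extraction, as are pairs with R above the plot cap (default 10).  Counting
them is a choice: only their plot exclusion is documented in the source
convention, and treating a complete single-allele loss as "no imbalance"
would be indefensible.

## Statistics

* **50:50 test**: Pearson chi-squared, df = 1, *no* continuity correction —
  with the correction none of the 23 published p-values verified; without
  it all do.  Zero imbalance events make a SNP not testable (reported with
  NaN, never silently dropped).
* **Bonferroni**: min(1, n·p), where n is the number of SNPs tested in the
  same stage (taken from the run context: retained discovery SNPs,
  screened SNPs for validation/combined, overlap size for cross-study
  pooling) — never hard-coded.  Adjusted p-values are computed from the
  full-precision raw p; published tables that multiplied the already
  rounded 2-decimal p can therefore differ by one unit in the last place
  (e.g. 0.50 here vs 0.51 rounded-then-multiplied).
* **Screening**: SNPs with raw p strictly below 0.10 advance to validation.
* **Pooling**: cohort pooling is element-wise count summation over a shared
  SNP set; cross-study pooling sums loss counts per SNP across studies and
  re-tests.  Heterogeneity between studies (different purity, platforms,
  cutoff dialects) is not modeled — pooling counts is exactly the published
  procedure, kept deliberately.
* **Clinical association**: sex → 2×2 Pearson chi-squared without
  continuity correction; TNM stage → Fisher exact on the 2×K table; age →
  two-sample t-test.  The t-test is pooled-variance (the era-default
  reading of "sample t-test"; Welch is a one-line change but is not the
  default).  Degenerate tables (empty margin, group of size < 2) return a
  flagged not-testable result.
* **Fisher exact (2×K)**: classical probability-mass rule — sum the
  probabilities of all fixed-margin tables no more probable than the
  observed one under the multivariate hypergeometric null.  Probabilities
  are computed in log space via `lgamma`; a relative tolerance of 1e-7
  absorbs float ties.  The implementation is exhaustively checked against
  an exact rational-arithmetic enumeration oracle and scipy's 2×2 routine.

## Calibration

The ideal mixture curve is ln((100 − p)/p) over the design
{0, 20, 40, 50, 60, 80, 100}% allele 1; the endpoints have no finite log
ratio and are excluded from fits (they remain as homozygote controls).
OLS of ln(N-ratio) on percent allele 1 over the five interior points gives
slope −0.0456, intercept 2.2822, r² = 0.9986.  The sign convention follows
the printed ideal equation (negative slope against % allele 1) even though
a literal allele-1/allele-2 ratio would slope positively; the package
reproduces the printed orientation rather than guessing which allele the
lab labelled "allele 1".  Default pass tolerances (|Δslope| ≤ 0.005,
|Δintercept| ≤ 0.25, r² ≥ 0.95) are Monte-Carlo-calibrated so that
noiseless data passes with wide margin and 5% multiplicative peak-area
noise passes in ≥ 95% of runs; they are analysis defaults, not instrument
specifications.

## Synthetic cohorts

The simulator generates what the pipeline consumes — peak-area tables for
both tissues — plus a ground-truth table.  Model: germline genotypes are
Hardy-Weinberg draws at the panel MAF (the risk allele's population
frequency is set to the MAF; which allele is minor is not recorded in the
panel source, and the heterozygote fraction 2·maf·(1 − maf) is unaffected).
A heterozygous pair carries a somatic event with probability π
(`event_prob`); the event disadvantages the non-risk allele with
probability β (`bias`; β = 0.5 is the 50:50 null) and is a single-copy
loss of the disadvantaged allele with probability `loss_fraction`,
otherwise a single-copy gain of the favored allele.  Events are
single-SNP, bi-state and clonal — enough to reproduce relative-loss /
relative-gain phenomenology without modeling amplification or subclones.
The tumor specimen mixes tumor and normal cells: each tumor allele's
expected signal is ρ·(tumor copies) + (1 − ρ)·(germline copies) with
purity ρ.  Peak areas are baseline × signal × independent log-normal noise
(`noise_sd`, multiplicative because areas are positive and ratio-scaled);
assays fail wholesale with probability `failure_rate`.  One seed drives a
single `numpy` generator stream, so identical configs give byte-identical
tables.

Defaults mirror the discovery cohort: 194 pairs, the 16-SNP panel,
ρ = 0.7 (tissue cores selected at ≥ 70% tumor cells), π = 0.25 (per-SNP
total-imbalance frequencies then fall in the observed 2–44% range),
β = 0.5, loss_fraction = 0.5, failure_rate = 0.05, baseline 1000.  No
empirical peak-area noise magnitude is published; noise_sd = 0.10 makes the
per-heterozygote false imbalance-call rate ≈ 4%, consistent with the
low-end published SNP rows, and lets the standard-curve module pass its
defaults.  What the simulator does **not** emulate: FFPE degradation
artifacts, plate/batch effects, linkage between SNPs (the two 8q24 SNPs
are simulated independently despite their LD), and subclonal heterogeneity
— so green tests demonstrate correctness of the analysis logic under the
stated generative model, not robustness to those real-data features.

Useful closed forms under this model (noiseless): a single-copy loss gives
R = 1/(1 − ρ), so the default 1.5 cutoff detects loss exactly when
ρ > 1/3; a single-copy gain gives R = 1/(1 + ρ), detected at the 0.67
cutoff when ρ > 0.493.  Both are exercised as exact tests.

### Bias recovery and its attenuation

`recover_bias` estimates β as n_loss_nonrisk / (total imbalance calls)
with a Wilson score interval.  Because noise produces symmetric false
calls, the estimand is diluted toward 0.5: with call fractions q_true from
events and q_false from noise, E[β̂] ≈ (q_true·β + q_false·0.5) /
(q_true + q_false).  Coverage of the *true* β is therefore slightly below
nominal for extreme β at large n.  The coverage experiment uses
β ∈ {0.5, 0.65, 0.8} × ρ ∈ {0.6, 0.8}, 400 pairs, 40 replicates per cell,
with thresholds (each cell ≥ 0.80, grid mean ≥ 0.875) derived from that
attenuation analysis.

## Problem sizes

Monte-Carlo experiments use single-SNP cohorts at MAF 0.5: 1000 replicates
of 150 pairs for the type-I error check, 240 cohorts of 400 pairs for the
coverage grid, and exhaustive Fisher verification over every 2×2 and 2×3
table with grand total ≤ 12.  These sizes give Monte-Carlo standard errors
small enough for 3-SE assertions while keeping the full suite fast.

## Known limitations

* The published per-patient clinical data are unavailable, so the reported
  stage/age correlations cannot be re-derived; the association operations
  are validated against closed forms and enumeration oracles instead.
* The 50:50 chi-squared test is asymptotic; at very small loss counts it is
  conservative relative to the exact binomial (an exact alternative is out
  of scope by design).
* `combine_counts` requires identical SNP sets across cohorts; partial
  overlap must be subset explicitly (as `run_combined` does).
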