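# asikit

Allele-specific somatic imbalance (ASI) analysis for paired normal/tumor
quantitative genotyping data.

## The problem

Cancer susceptibility alleles found by GWAS may be under somatic selection:
in a tumor arising in a heterozygous carrier, the risk allele may be
preferentially retained or gained while the other allele is lost.
Quantitative genotyping (e.g. mass-spectrometry primer extension) reports a
peak area per allele, so a heterozygous normal/tumor pair can be scored for
a shift in allele balance.  `asikit` implements that analysis end to end
for a panel of colorectal-cancer GWAS SNPs: genotype calling and QC from
peak areas, R-ratio scoring and imbalance calling, a chi-squared test of
preferential loss, cross-cohort and cross-study pooling, mixture
standard-curve calibration, clinical covariate association, and a
ground-truth cohort simulator for power and calibration experiments.

## The statistic

For each SNP with a heterozygous normal, with peak areas oriented so allele
1 is the GWAS risk allele:

    N-ratio = normal  area_risk / area_nonrisk
    T-ratio = tumor   area_risk / area_nonrisk
    R-ratio = N-ratio / T-ratio

R > 1.5 is called relative loss of the risk allele, R < 0.67 relative loss
of the non-risk allele (the chromatogram-study dialect 1.67/0.60 ships as a
preset).  When the normal assay failed but the tumor is heterozygous, the
N-ratio is imputed as the ratio of per-allele mean areas over all
heterozygous normals at that SNP.  Per SNP, the counts of risk-allele
losses *a* and non-risk-allele losses *b* are tested against a 50:50 split
with the df = 1 Pearson statistic

    chi2 = (a − e)²/e + (b − e)²/e,   e = (a + b)/2

without continuity correction, and Bonferroni-adjusted by the number of
SNPs in the analysis stage.  Assay sensitivity is verified by fitting
ln(N-ratio) against the percent of allele 1 in known DNA mixtures
{20, 40, 50, 60, 80}%, whose ideal curve is ln((100 − p)/p) with OLS
coefficients slope = −0.0456, intercept = 2.2822.

## Worked example

Simulate a discovery-style cohort (194 pairs, the 16-SNP panel) and run the
discovery stage:

```sh
asikit simulate --out sim/ --seed 1
asikit discover --peaks sim/peaks.tsv --panel sim/panel.tsv --out disc/
```

`disc/discovery_report.tsv` contains one row per SNP in publication layout,
e.g. (seed 1):

```
snp_id     risk_allele  nonrisk_allele  risk_allele_lost  nonrisk_allele_lost  total_imbalance  p     p_adjusted
rs4939827  T            C               7 (8%)            21 (23%)             28/93 (30%)      0.01  0.13
rs10936599 C            T               10 (14%)          4 (5%)               14/74 (19%)      0.11  1.00
...
```

Reading the first row: of 93 heterozygous pairs at rs4939827, 7 tumors lost
the risk allele and 21 lost the non-risk allele (30% total imbalance); the
50:50 test gives p = 0.01, which no longer reaches significance after
Bonferroni correction for the 16 SNPs tested (p = 0.13).  The screened SNPs
(raw p < 0.10) are listed in `disc/screened_snps.txt` and feed
`asikit validate`; `asikit combine` pools cohort counts, `asikit meta`
pools loss counts with external studies, `asikit clinical` tests imbalance
against sex (chi-squared), TNM stage (Fisher exact) and age (two-sample
t-test), and `asikit calibrate` fits mixture standard curves.

The same workflow is available as plain functions
(`asikit.pipeline.run_discovery`, `run_validation`, `run_combined`,
`run_meta`, `run_clinical`) operating on pandas DataFrames.

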