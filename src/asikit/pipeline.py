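"""Stage orchestration for the full imbalance study workflow.

The study runs as discovery -> screen -> validation -> combined -> meta ->
clinical.  Each stage is a plain function over DataFrames so it can be used
from Python directly; the command-line layer in :mod:`asikit.cli` is a thin
wrapper.  Bonferroni n for each stage is the number of SNPs tested at that
stage (retained discovery SNPs, screened SNPs, meta-overlap SNPs), taken
from the run context.  Rounding happens only at report rendering.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import asi_stats, data_io, genotype_qc, imbalance

log = logging.getLogger(__name__)


@dataclasses.dataclass
class AnalysisSettings:
    """Tunable analysis parameters (config-file surface)."""

    dialect: str = "standard"
    floor_fraction: float = genotype_qc.DEFAULT_FLOOR_FRACTION
    het_band: float = genotype_qc.DEFAULT_HET_BAND
    max_failure_rate: float = genotype_qc.DEFAULT_MAX_FAILURE_RATE
    maf_floor: float = genotype_qc.DEFAULT_MAF_FLOOR
    alpha_screen: float = asi_stats.DEFAULT_ALPHA_SCREEN
    plot_cap: float = imbalance.DEFAULT_PLOT_CAP

    @property
    def cutoffs(self) -> imbalance.Cutoffs:
        return imbalance.DIALECTS[self.dialect]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisSettings":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for section in ("genotype", "qc", "panel", "imbalance", "stats"):
            flat.update(raw.get(section, {}) or {})
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in flat.items() if k in known})


@dataclasses.dataclass
class CohortAnalysis:
    """All intermediate and final tables of one cohort's analysis."""

    qc: pd.DataFrame            # per-SNP failure rates and retention
    pairs: pd.DataFrame         # informative normal/tumor pairs
    pair_results: pd.DataFrame  # per-pair ratios and calls
    counts: pd.DataFrame        # per-SNP imbalance counts
    tests: pd.DataFrame         # per-SNP 50:50 chi-squared results


def analyze_cohort(peaks: pd.DataFrame, panel: pd.DataFrame,
                   settings: AnalysisSettings | None = None,
                   snp_ids: list[str] | None = None,
                   n_tests: int | None = None) -> CohortAnalysis:
    """Run QC, pair selection, R-ratio scoring and the 50:50 test.

    ``snp_ids`` restricts analysis to a subset of the panel (validation
    stage); ``n_tests`` overrides the Bonferroni count (defaults to the
    number of SNPs surviving QC).
    """
    settings = settings or AnalysisSettings()
    if snp_ids is not None:
        missing = sorted(set(snp_ids) - set(peaks["snp_id"].unique()))
        if missing:
            raise data_io.TableValidationError(
                f"SNPs absent from peak table: {missing}")
        peaks = peaks[peaks["snp_id"].isin(snp_ids)].reset_index(drop=True)
        panel = panel[panel["snp_id"].isin(snp_ids)].reset_index(drop=True)
    calls = genotype_qc.call_genotypes(peaks, floor_fraction=settings.floor_fraction,
                                       het_band=settings.het_band)
    qc = genotype_qc.qc_by_snp(calls, settings.max_failure_rate)
    retained = set(qc.loc[qc["retained"], "snp_id"])
    dropped = sorted(set(qc["snp_id"]) - retained)
    if dropped:
        log.info("stage=qc dropped_snps=%s", ",".join(dropped))
    calls = calls[calls["snp_id"].isin(retained)].reset_index(drop=True)
    peaks_kept = peaks[peaks["snp_id"].isin(retained)].reset_index(drop=True)
    pairs = genotype_qc.select_het_pairs(calls)
    pair_results = imbalance.evaluate_pairs(peaks_kept, calls, pairs,
                                            settings.cutoffs, settings.plot_cap)
    counts = imbalance.summarize_all(pair_results, sorted(retained))
    if n_tests is None:
        n_tests = max(1, len(counts))
    tests = asi_stats.evaluate_counts(counts, n_tests=n_tests)
    log.info("stage=analysis snps=%d pairs=%d hets=%d imbalances=%d",
             len(counts), len(pairs), int(counts["n_het"].sum()),
             int(counts["n_total_imbalance"].sum()))
    return CohortAnalysis(qc=qc, pairs=pairs, pair_results=pair_results,
                          counts=counts, tests=tests)


def run_discovery(peaks: pd.DataFrame, panel: pd.DataFrame,
                  settings: AnalysisSettings | None = None,
                  ) -> tuple[CohortAnalysis, list[str]]:
    """Discovery stage: panel MAF screen, full analysis, then the p < 0.10
    screen that selects SNPs for validation."""
    settings = settings or AnalysisSettings()
    screened_panel = genotype_qc.screen_panel(panel, settings.maf_floor)
    analysis = analyze_cohort(peaks, screened_panel, settings)
    validation_snps = asi_stats.screen_for_validation(analysis.tests,
                                                      settings.alpha_screen)
    log.info("stage=discovery screened=%s", ",".join(validation_snps) or "-")
    return analysis, validation_snps


def run_validation(peaks: pd.DataFrame, panel: pd.DataFrame,
                   screened_snps: list[str],
                   settings: AnalysisSettings | None = None,
                   ) -> CohortAnalysis | None:
    """Validation stage: same pipeline on the screened SNPs only, with
    Bonferroni n equal to the screened count."""
    if not screened_snps:
        log.warning("stage=validation no screened SNPs: nothing to do")
        return None
    return analyze_cohort(peaks, panel, settings, snp_ids=screened_snps,
                          n_tests=len(screened_snps))


def run_combined(discovery_counts: pd.DataFrame, validation_counts: pd.DataFrame,
                 n_tests: int | None = None) -> pd.DataFrame:
    """Pool the two cohorts' counts per SNP and re-test (Bonferroni n =
    number of screened SNPs)."""
    snps = set(validation_counts["snp_id"])
    disc = discovery_counts[discovery_counts["snp_id"].isin(snps)]
    combined = asi_stats.combine_counts(disc, validation_counts)
    return asi_stats.evaluate_counts(combined,
                                 n_tests=n_tests if n_tests is not None else len(combined))


def run_meta(own_counts: pd.DataFrame, published: pd.DataFrame | None,
             study_id: str = "this_study") -> pd.DataFrame:
    """Cross-study pooling of loss counts over the SNPs shared with the
    published studies, with Bonferroni n = overlap size."""
    if published is None or published.empty:
        log.info("stage=meta no external study counts supplied: skipped")
        return pd.DataFrame()
    overlap = set(published["snp_id"]) & set(own_counts["snp_id"])
    own = own_counts[own_counts["snp_id"].isin(overlap)].copy()
    own.insert(0, "study_id", study_id)
    pub = published[published["snp_id"].isin(overlap)]
    return asi_stats.meta_combine(
        own[data_io.STUDY_COUNT_COLUMNS], pub[data_io.STUDY_COUNT_COLUMNS],
        n_tests=len(overlap))


def run_clinical(pair_results: pd.DataFrame, clinical: pd.DataFrame,
                 n_tests: int | None = None) -> pd.DataFrame:
    """Per-SNP association of imbalance presence with sex, stage and age."""
    snps = sorted(pair_results["snp_id"].unique())
    if n_tests is None:
        n_tests = max(1, len(snps))
    merged = pair_results.merge(clinical, on="sample_id", how="left")
    merged["imbalanced"] = merged["call"] != imbalance.CALL_NO_IMBALANCE
    rows = []
    for snp in snps:
        sub = merged[merged["snp_id"] == snp]
        with_sex = sub.dropna(subset=["sex"])
        rows.append(asi_stats.assoc_sex(with_sex["imbalanced"], with_sex["sex"],
                                        snp, n_tests))
        with_stage = sub.dropna(subset=["stage"])
        rows.append(asi_stats.assoc_stage(with_stage["imbalanced"],
                                          with_stage["stage"], snp, n_tests))
        with_age = sub.dropna(subset=["age"])
        rows.append(asi_stats.assoc_age(
            with_age.loc[with_age["imbalanced"], "age"],
            with_age.loc[~with_age["imbalanced"], "age"], snp, n_tests))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def write_stage_report(analysis: CohortAnalysis, panel: pd.DataFrame,
                       out_dir: str | Path, stage: str) -> None:
    """Write the per-pair table, count table and rendered report of a stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis.pair_results.to_csv(out / f"{stage}_pairs.tsv", sep="\t", index=False)
    analysis.counts.to_csv(out / f"{stage}_counts.tsv", sep="\t", index=False)
    analysis.tests.to_csv(out / f"{stage}_tests.tsv", sep="\t", index=False)
    merged = analysis.tests.merge(
        panel[["snp_id", "risk_allele", "nonrisk_allele"]], on="snp_id")
    testable = merged.dropna(subset=["p"]).sort_values("p", kind="stable")
    data_io.write_report(testable, out / f"{stage}_report.tsv")
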