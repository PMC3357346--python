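"""Synthetic paired normal/tumor cohorts with known somatic ground truth.

The generator emulates quantitative-genotyping peak-area tables for a panel
of GWAS SNPs.  Germline genotypes are drawn under Hardy-Weinberg from each
SNP's minor allele frequency; heterozygous pairs carry a somatic allelic
event with probability ``event_prob``.  An event disadvantages the non-risk
allele with probability ``bias`` (0.5 encodes the no-preferential-selection
null) and is either a single-copy loss of the disadvantaged allele or a
single-copy gain of the favored one (``loss_fraction`` splits the two).  The
tumor specimen is a mixture of tumor and contaminating normal cells: each
tumor allele's expected signal is purity * (tumor copies) + (1 - purity) *
(germline copies).  Peak areas are the baseline times the expected signal
times independent multiplicative log-normal noise; whole assays fail (both
areas zero) with probability ``failure_rate``.

Defaults mirror the discovery cohort: 194 pairs on the 16-SNP panel, 70%
tumor purity (tissue cores selected for >=70% tumor cells), and an event
probability chosen so per-SNP imbalance frequencies fall in the observed
2-44% range.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import asi_stats, genotype_qc, imbalance
from .data_io import PEAK_COLUMNS

# 16-SNP colorectal-cancer GWAS panel: risk allele, non-risk allele, dbSNP
# minor allele frequency, locus label, low-MAF exception flag.
PANEL_ROWS = [
    ("rs10411210", "C", "T", 0.21, "RHPN2", False),
    ("rs10936599", "C", "T", 0.30, "MYNN", False),
    ("rs11169552", "C", "T", 0.24, "ATF1/DIP2B", False),
    ("rs16892766", "C", "A", 0.07, "EIF3H", True),
    ("rs3802842", "C", "A", 0.31, "C11orf93", False),
    ("rs4444235", "C", "T", 0.44, "BMP4", False),
    ("rs4779584", "T", "C", 0.46, "SCG5/GREM1", False),
    ("rs4939827", "T", "C", 0.38, "SMAD7", False),
    ("rs6687758", "G", "A", 0.22, "1q41", False),
    ("rs6691170", "T", "G", 0.26, "1q41", False),
    ("rs6983267", "G", "T", 0.44, "8q24", False),
    ("rs7014346", "A", "G", 0.33, "8q24", False),
    ("rs7136702", "T", "C", 0.46, "LARP4/DIP2B", False),
    ("rs719725", "A", "C", 0.33, "9p24", False),
    ("rs961253", "A", "C", 0.29, "BMP2", False),
    ("rs9929218", "G", "A", 0.25, "CDH1", False),
]


def default_panel() -> pd.DataFrame:
    """The 16-SNP study panel as a panel DataFrame."""
    return pd.DataFrame(PANEL_ROWS, columns=["snp_id", "risk_allele",
                                             "nonrisk_allele", "maf",
                                             "locus_label", "maf_exception"])


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one synthetic cohort.

    purity: tumor-cell fraction of the tumor specimen.
    event_prob: probability a heterozygous pair carries a somatic event.
    bias: probability the event disadvantages the non-risk allele.
    loss_fraction: fraction of events that are single-copy losses (the rest
        are single-copy gains of the favored allele).
    noise_sd: standard deviation of log-normal multiplicative area noise.
    failure_rate: per-assay probability that both peak areas are zero.
    """

    n_pairs: int = 194
    panel: pd.DataFrame | None = None
    purity: float = 0.7
    event_prob: float = 0.25
    bias: float = 0.5
    loss_fraction: float = 0.5
    noise_sd: float = 0.10
    failure_rate: float = 0.05
    baseline_area: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be at least 1")
        if self.baseline_area <= 0:
            raise ValueError("baseline_area must be positive")
        for name in ("purity", "event_prob", "bias", "loss_fraction",
                     "failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def resolved_panel(self) -> pd.DataFrame:
        return default_panel() if self.panel is None else self.panel


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort.

    Returns ``(peaks, truth)``: a peak-area table covering both tissues in
    the standard schema, and a per-(sample, SNP) ground-truth table with
    columns sample_id, snp_id, genotype, event, event_type, favored_allele,
    tumor_copies_risk, tumor_copies_nonrisk.  Identical configs (including
    seed) produce identical output.
    """
    panel = config.resolved_panel()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_pairs, len(panel)
    width = max(4, len(str(n)))
    samples = np.array([f"S{i + 1:0{width}d}" for i in range(n)])
    snps = panel["snp_id"].to_numpy()
    maf = panel["maf"].to_numpy(float)

    # germline risk-allele copy count under Hardy-Weinberg; the risk allele
    # population frequency is taken to be the panel MAF
    g_risk = rng.binomial(2, maf[np.newaxis, :], size=(n, m))
    g_nonrisk = 2 - g_risk
    het = g_risk == 1

    event = het & (rng.random((n, m)) < config.event_prob)
    favors_risk = rng.random((n, m)) < config.bias
    is_loss = rng.random((n, m)) < config.loss_fraction

    t_risk = g_risk.astype(float).copy()
    t_nonrisk = g_nonrisk.astype(float).copy()
    # loss removes the disadvantaged allele's copy; gain duplicates the
    # favored allele's copy
    lose_nonrisk = event & favors_risk & is_loss
    gain_risk = event & favors_risk & ~is_loss
    lose_risk = event & ~favors_risk & is_loss
    gain_nonrisk = event & ~favors_risk & ~is_loss
    t_nonrisk[lose_nonrisk] = 0.0
    t_risk[gain_risk] = 2.0
    t_risk[lose_risk] = 0.0
    t_nonrisk[gain_nonrisk] = 2.0

    rho = config.purity
    sig_n_risk = g_risk.astype(float)
    sig_n_nonrisk = g_nonrisk.astype(float)
    sig_t_risk = rho * t_risk + (1.0 - rho) * g_risk
    sig_t_nonrisk = rho * t_nonrisk + (1.0 - rho) * g_nonrisk

    def areas(signal: np.ndarray) -> np.ndarray:
        noise = np.exp(rng.normal(0.0, config.noise_sd, size=signal.shape)) \
            if config.noise_sd > 0 else 1.0
        return config.baseline_area * signal * noise

    a_n_risk, a_n_nonrisk = areas(sig_n_risk), areas(sig_n_nonrisk)
    a_t_risk, a_t_nonrisk = areas(sig_t_risk), areas(sig_t_nonrisk)
    fail_n = rng.random((n, m)) < config.failure_rate
    fail_t = rng.random((n, m)) < config.failure_rate
    a_n_risk[fail_n] = 0.0
    a_n_nonrisk[fail_n] = 0.0
    a_t_risk[fail_t] = 0.0
    a_t_nonrisk[fail_t] = 0.0

    sample_col = np.repeat(samples, m)
    snp_col = np.tile(snps, n)
    peaks = pd.concat([
        pd.DataFrame({"sample_id": sample_col, "snp_id": snp_col,
                      "tissue": "normal",
                      "area_risk": a_n_risk.ravel(),
                      "area_nonrisk": a_n_nonrisk.ravel()}),
        pd.DataFrame({"sample_id": sample_col, "snp_id": snp_col,
                      "tissue": "tumor",
                      "area_risk": a_t_risk.ravel(),
                      "area_nonrisk": a_t_nonrisk.ravel()}),
    ], ignore_index=True)[PEAK_COLUMNS]

    genotype = np.where(het, "het",
                        np.where(g_risk == 2, "hom_risk", "hom_nonrisk"))
    event_type = np.full((n, m), "none", dtype=object)
    event_type[event & is_loss] = "loss"
    event_type[event & ~is_loss] = "gain"
    favored = np.full((n, m), "", dtype=object)
    favored[event & favors_risk] = "risk"
    favored[event & ~favors_risk] = "nonrisk"
    truth = pd.DataFrame({
        "sample_id": sample_col, "snp_id": snp_col,
        "genotype": genotype.ravel(), "event": event.ravel(),
        "event_type": event_type.ravel(), "favored_allele": favored.ravel(),
        "tumor_copies_risk": t_risk.ravel().astype(int),
        "tumor_copies_nonrisk": t_nonrisk.ravel().astype(int),
    })
    return peaks, truth


@dataclasses.dataclass(frozen=True)
class BiasEstimate:
    """Estimated preferential-loss bias with a Wilson binomial interval."""

    beta_hat: float
    ci_low: float
    ci_high: float
    n_calls: int
    level: float

    def covers(self, beta: float) -> bool:
        return self.ci_low <= beta <= self.ci_high


def recover_bias(counts: imbalance.ImbalanceCounts | tuple[int, int],
                 level: float = 0.95) -> BiasEstimate:
    """Estimate the preferential bias from pipeline imbalance counts.

    beta_hat = n_loss_nonrisk / (n_loss_risk + n_loss_nonrisk) — the
    fraction of imbalance calls that disadvantage the non-risk allele —
    with a Wilson score interval at the given level.
    """
    if isinstance(counts, imbalance.ImbalanceCounts):
        k, n = counts.n_loss_nonrisk, counts.n_total_imbalance
    else:
        loss_risk, loss_nonrisk = counts
        k, n = loss_nonrisk, loss_risk + loss_nonrisk
    if n == 0:
        raise asi_stats.NotTestableError("no imbalance calls: bias not estimable")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return BiasEstimate(k / n, float(lo), float(hi), n, level)


def analyze_single_snp(peaks: pd.DataFrame, snp_id: str,
                       cutoffs: imbalance.Cutoffs = imbalance.DIALECTS["standard"],
                       ) -> imbalance.ImbalanceCounts:
    """Run the genotype -> pair -> R-ratio pipeline and count imbalances for
    one SNP (convenience for simulation experiments)."""
    calls = genotype_qc.call_genotypes(peaks)
    pairs = genotype_qc.select_het_pairs(calls)
    results = imbalance.evaluate_pairs(peaks, calls, pairs, cutoffs)
    return imbalance.summarize_snp(results, snp_id)


def power_experiment(grid: Iterable[Mapping[str, float]], alpha: float = 0.05,
                     n_reps: int = 200, seed: int = 0,
                     base_config: SimConfig | None = None) -> pd.DataFrame:
    """Monte-Carlo rejection rates of the 50:50 test over a parameter grid.

    ``grid`` is an iterable of dicts with any of the keys n_pairs, bias,
    purity, event_prob (missing keys fall back to ``base_config``).  Each
    cell simulates ``n_reps`` single-SNP cohorts (maf 0.5 for maximal
    heterozygosity), runs the full call/score pipeline, and records the
    fraction of replicates in which the 50:50 chi-squared test rejects at
    ``alpha``.  Replicates without any imbalance call are not testable and
    count as non-rejections.
    """
    snp = pd.DataFrame([("rs_sim", "A", "C", 0.5, "sim", False)],
                       columns=["snp_id", "risk_allele", "nonrisk_allele",
                                "maf", "locus_label", "maf_exception"])
    base = base_config if base_config is not None else SimConfig(panel=snp)
    root = np.random.default_rng(seed)
    rows = []
    for cell in grid:
        rejections = 0
        testable = 0
        for _ in range(n_reps):
            cfg = dataclasses.replace(
                base, panel=snp,
                n_pairs=int(cell.get("n_pairs", base.n_pairs)),
                bias=float(cell.get("bias", base.bias)),
                purity=float(cell.get("purity", base.purity)),
                event_prob=float(cell.get("event_prob", base.event_prob)),
                seed=int(root.integers(0, 2**31 - 1)))
            peaks, _ = simulate_cohort(cfg)
            counts = analyze_single_snp(peaks, "rs_sim")
            try:
                _, p = asi_stats.chi2_5050(counts.n_loss_risk,
                                           counts.n_loss_nonrisk)
            except asi_stats.NotTestableError:
                continue
            testable += 1
            if p < alpha:
                rejections += 1
        rows.append({**cell, "n_reps": n_reps, "n_testable": testable,
                     "rejection_rate": rejections / n_reps})
    return pd.DataFrame(rows)
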