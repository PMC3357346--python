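"""Statistical testing of allele-specific imbalance counts.

The core test asks whether, among heterozygous tumors showing imbalance at a
SNP, losses split 50:50 between the risk and non-risk allele.  It is the
one-degree-of-freedom Pearson chi-squared goodness-of-fit statistic

    chi2 = (a - e)^2/e + (b - e)^2/e,   e = (a + b)/2,

without continuity correction, with the upper-tail chi-squared(1) p-value.
Multiple testing within an analysis stage is handled by Bonferroni
multiplication, with n equal to the number of SNPs tested at that stage.
Counts can be pooled across cohorts of one study (element-wise sums) and
across studies (summing published loss counts into a single 50:50 test).

Clinical covariate association uses the field-standard mapping: 2x2 Pearson
chi-squared for sex, Fisher's exact test (probability-mass rule, needed for
2xK stage tables) for TNM stage, and a pooled-variance two-sample t-test for
age at diagnosis.
"""

from __future__ import annotations

import dataclasses
import math
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA_SCREEN = 0.10


class NotTestableError(ValueError):
    """The requested test is undefined for these inputs (e.g. zero counts)."""


@dataclasses.dataclass(frozen=True)
class AsiTestResult:
    """Chi-squared 50:50 test of one SNP's loss counts."""

    snp_id: str
    n_loss_risk: int
    n_loss_nonrisk: int
    chi2: float
    p: float
    p_adjusted: float
    n_tests: int
    df: int = 1


@dataclasses.dataclass(frozen=True)
class ClinicalAssociation:
    snp_id: str
    covariate: str            # sex | stage | age
    test: str                 # chi_squared | fisher_exact | two_sample_t
    statistic: float
    p: float
    p_adjusted: float
    testable: bool = True


def chi2_5050(a: int, b: int) -> tuple[float, float]:
    """Chi-squared test (df=1, no continuity correction) of counts (a, b)
    against an expected 50:50 split; returns (statistic, p)."""
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0:
        raise NotTestableError("no imbalance events: 50:50 test undefined")
    e = (a + b) / 2.0
    chi2 = (a - e) ** 2 / e + (b - e) ** 2 / e
    return chi2, float(stats.chi2.sf(chi2, df=1))


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value min(1, n_tests * p)."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    return min(1.0, n_tests * p)


def evaluate_counts(counts: pd.DataFrame, n_tests: int | None = None) -> pd.DataFrame:
    """Run the 50:50 test on a per-SNP imbalance count table.

    ``counts`` needs columns snp_id, n_het, n_loss_risk, n_loss_nonrisk.
    ``n_tests`` defaults to the number of SNPs in the table.  SNPs with zero
    imbalance events are reported with NaN statistics (not testable).
    """
    if n_tests is None:
        n_tests = len(counts)
    rows = []
    for r in counts.itertuples(index=False):
        try:
            chi2, p = chi2_5050(int(r.n_loss_risk), int(r.n_loss_nonrisk))
            p_adj = bonferroni(p, n_tests)
        except NotTestableError:
            chi2, p, p_adj = math.nan, math.nan, math.nan
        rows.append({"snp_id": r.snp_id, "n_het": int(r.n_het),
                     "n_loss_risk": int(r.n_loss_risk),
                     "n_loss_nonrisk": int(r.n_loss_nonrisk),
                     "chi2": chi2, "p": p, "p_adjusted": p_adj,
                     "n_tests": n_tests})
    return pd.DataFrame(rows)


def screen_for_validation(results: pd.DataFrame,
                          alpha_screen: float = DEFAULT_ALPHA_SCREEN) -> list[str]:
    """SNPs whose raw p-value is strictly below the screening threshold,
    sorted by p-value (then snp_id for ties)."""
    testable = results.dropna(subset=["p"])
    hits = testable[testable["p"] < alpha_screen]
    hits = hits.sort_values(["p", "snp_id"], kind="stable")
    return hits["snp_id"].tolist()


def combine_counts(*tables: pd.DataFrame) -> pd.DataFrame:
    """Element-wise sum of per-SNP count tables from multiple cohorts.

    All tables must cover the same SNP set; counts are summed per SNP.
    """
    if not tables:
        raise ValueError("no tables to combine")
    snp_sets = [set(t["snp_id"]) for t in tables]
    if any(s != snp_sets[0] for s in snp_sets[1:]):
        raise ValueError("cohort tables cover different SNP sets: "
                         f"{sorted(set.union(*snp_sets) - set.intersection(*snp_sets))}")
    stacked = pd.concat(tables, ignore_index=True)
    out = (stacked.groupby("snp_id", sort=True, as_index=False)
           [["n_het", "n_loss_risk", "n_loss_nonrisk"]].sum())
    out["n_total_imbalance"] = out["n_loss_risk"] + out["n_loss_nonrisk"]
    return out


def meta_combine(own: pd.DataFrame, published: pd.DataFrame | None = None,
                 n_tests: int | None = None) -> pd.DataFrame:
    """Pool loss counts across studies and re-test each SNP against 50:50.

    ``own`` and ``published`` are study-count frames (columns study_id,
    snp_id, n_het, n_loss_risk, n_loss_nonrisk); only SNPs present in ``own``
    are tested.  ``n_tests`` defaults to the number of SNPs tested.
    """
    frames = [own] if published is None or published.empty else [own, published]
    stacked = pd.concat(frames, ignore_index=True)
    stacked = stacked[stacked["snp_id"].isin(set(own["snp_id"]))]
    pooled = (stacked.groupby("snp_id", sort=True, as_index=False)
              [["n_het", "n_loss_risk", "n_loss_nonrisk"]].sum())
    return evaluate_counts(pooled, n_tests=n_tests)


# --- Fisher's exact test for 2xK tables ------------------------------------

def _log_table_prob(row1: Sequence[int], col_sums: Sequence[int],
                    r1: int, n: int) -> float:
    # P(table) = prod_j C(c_j, a_j) / C(n, r1) under fixed margins
    logp = -(lgamma(n + 1) - lgamma(r1 + 1) - lgamma(n - r1 + 1))
    for a, c in zip(row1, col_sums):
        logp += lgamma(c + 1) - lgamma(a + 1) - lgamma(c - a + 1)
    return logp


def fisher_exact_2xk(table: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2xK contingency table.

    Uses the classical probability-mass rule: under the fixed-margins
    multivariate hypergeometric null, sum the probabilities of all tables no
    more probable than the observed one.  A small relative tolerance guards
    the floating-point comparison of equal-probability tables.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2xK table")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    col_sums = t.sum(axis=0)
    t = t[:, col_sums > 0]
    col_sums = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    if n == 0 or r1 == 0 or r1 == n or t.shape[1] < 2:
        raise NotTestableError("degenerate margins: Fisher test undefined")
    obs_logp = _log_table_prob(t[0], col_sums, r1, n)
    threshold = obs_logp + 1e-7
    k = len(col_sums)

    total = 0.0
    row1 = [0] * k

    def recurse(j: int, remaining: int, logp_partial: float) -> None:
        nonlocal total
        if j == k - 1:
            if remaining > col_sums[j]:
                return
            row1[j] = remaining
            logp = logp_partial + (lgamma(col_sums[j] + 1)
                                   - lgamma(remaining + 1)
                                   - lgamma(col_sums[j] - remaining + 1))
            if logp <= threshold:
                total += math.exp(logp)
            return
        lo = max(0, remaining - int(col_sums[j + 1:].sum()))
        hi = min(col_sums[j], remaining)
        for a in range(lo, hi + 1):
            row1[j] = a
            recurse(j + 1, remaining - a,
                    logp_partial + lgamma(col_sums[j] + 1)
                    - lgamma(a + 1) - lgamma(col_sums[j] - a + 1))

    norm = lgamma(n + 1) - lgamma(r1 + 1) - lgamma(n - r1 + 1)
    recurse(0, r1, -norm)
    return min(1.0, total)


# --- clinical covariate association ----------------------------------------

def _adjust(p: float, n_tests: int) -> float:
    return bonferroni(p, n_tests) if not math.isnan(p) else math.nan


def assoc_sex(imbalance_flags: Sequence[bool], sexes: Sequence[str],
              snp_id: str = "", n_tests: int = 1) -> ClinicalAssociation:
    """2x2 Pearson chi-squared (no continuity correction) of imbalance
    presence against sex."""
    flags = np.asarray(imbalance_flags, dtype=bool)
    sex = np.asarray(sexes, dtype=object)
    table = np.array([[int((flags & (sex == s)).sum()) for s in ("female", "male")],
                      [int((~flags & (sex == s)).sum()) for s in ("female", "male")]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ClinicalAssociation(snp_id, "sex", "chi_squared",
                                   math.nan, math.nan, math.nan, testable=False)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ClinicalAssociation(snp_id, "sex", "chi_squared", float(chi2),
                               float(p), _adjust(float(p), n_tests))


def assoc_stage(imbalance_flags: Sequence[bool], stages: Sequence[str],
                snp_id: str = "", n_tests: int = 1) -> ClinicalAssociation:
    """Fisher exact test of imbalance presence against TNM stage (2xK)."""
    flags = np.asarray(imbalance_flags, dtype=bool)
    stage = np.asarray(stages, dtype=object)
    levels = [s for s in ("I", "II", "III", "IV") if (stage == s).any()]
    table = np.array([[int(((stage == s) & (flags == present)).sum())
                       for s in levels] for present in (True, False)])
    try:
        p = fisher_exact_2xk(table)
    except NotTestableError:
        return ClinicalAssociation(snp_id, "stage", "fisher_exact",
                                   math.nan, math.nan, math.nan, testable=False)
    return ClinicalAssociation(snp_id, "stage", "fisher_exact", math.nan,
                               p, _adjust(p, n_tests))


def assoc_age(ages_imbalanced: Sequence[float], ages_balanced: Sequence[float],
              snp_id: str = "", n_tests: int = 1) -> ClinicalAssociation:
    """Pooled-variance two-sample t-test comparing mean age at diagnosis
    between imbalanced and balanced tumors."""
    a = np.asarray(ages_imbalanced, dtype=float)
    b = np.asarray(ages_balanced, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return ClinicalAssociation(snp_id, "age", "two_sample_t",
                                   math.nan, math.nan, math.nan, testable=False)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return ClinicalAssociation(snp_id, "age", "two_sample_t", float(t),
                               float(p), _adjust(float(p), n_tests))
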