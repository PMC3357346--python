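"""R-ratio scoring and allele-specific imbalance calling.

For each informative pair the N-ratio (normal risk/non-risk peak-area ratio)
is divided by the T-ratio (the same ratio in the tumor) to give the R-ratio.
An R-ratio far from 1 means the tumor's allele balance has shifted relative
to the germline: R above the upper cutoff is relative loss of the risk
allele, R below the lower cutoff relative loss of the non-risk allele.  The
default cutoffs (1.5, 0.67) follow the quantitative-genotyping dialect; the
chromatogram-based studies used (1.67, 0.60), shipped as the ``published``
preset.  When the normal assay failed but the tumor is heterozygous, the
normal ratio is imputed from the per-allele mean areas of all heterozygous
normals at that SNP.

Complete single-allele loss in the tumor (one peak area exactly 0) yields an
R-ratio sentinel of +inf (risk peak absent) or 0 (non-risk peak absent); such
pairs receive the corresponding loss call but are excluded from plot-ready
value extraction, as are pairs with R above the plot cap.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from . import genotype_qc

log = logging.getLogger(__name__)

CALL_LOSS_RISK = "loss_risk"
CALL_LOSS_NONRISK = "loss_nonrisk"
CALL_NO_IMBALANCE = "no_imbalance"

DEFAULT_PLOT_CAP = 10.0


@dataclasses.dataclass(frozen=True)
class Cutoffs:
    """R-ratio imbalance cutoffs; both boundaries are strict."""

    upper: float = 1.5
    lower: float = 0.67

    def __post_init__(self) -> None:
        if not 0 < self.lower < 1 < self.upper:
            raise ValueError(f"require 0 < lower < 1 < upper, got {self}")


DIALECTS = {"standard": Cutoffs(1.5, 0.67), "published": Cutoffs(1.67, 0.60)}


@dataclasses.dataclass(frozen=True)
class PairResult:
    sample_id: str
    snp_id: str
    n_ratio: float
    t_ratio: float
    r_ratio: float
    call: str
    imputed_normal: bool
    plot_eligible: bool


@dataclasses.dataclass(frozen=True)
class ImbalanceCounts:
    """Per-SNP imbalance counts over heterozygous pairs."""

    snp_id: str
    n_het: int
    n_loss_risk: int
    n_loss_nonrisk: int

    @property
    def n_total_imbalance(self) -> int:
        return self.n_loss_risk + self.n_loss_nonrisk


class UndefinedRatioError(ValueError):
    """Both allele peak areas are zero: no ratio exists."""


def allele_ratio(area_1: float, area_2: float) -> float:
    """Peak-area ratio allele1/allele2 with sentinels: 0 when the numerator
    peak is absent, +inf when the denominator peak is absent."""
    if area_1 < 0 or area_2 < 0:
        raise ValueError("peak areas must be non-negative")
    if area_1 == 0 and area_2 == 0:
        raise UndefinedRatioError("both allele peak areas are zero")
    if area_2 == 0:
        return math.inf
    return area_1 / area_2


def r_ratio(normal_ratio: float, tumor_ratio: float) -> float:
    """Normal allele ratio divided by tumor allele ratio.

    The normal must be informative (finite, positive ratio).  A tumor ratio
    of 0 (risk peak absent) maps to +inf; a tumor ratio of +inf (non-risk
    peak absent) maps to 0.
    """
    if not (math.isfinite(normal_ratio) and normal_ratio > 0):
        raise ValueError(f"normal ratio must be finite and positive, got {normal_ratio}")
    if tumor_ratio == 0:
        return math.inf
    if math.isinf(tumor_ratio):
        return 0.0
    return normal_ratio / tumor_ratio


def impute_normal_ratio(snp_id: str, calls: pd.DataFrame,
                        peaks: pd.DataFrame) -> float:
    """Surrogate normal ratio for a failed normal assay: the ratio of the
    per-allele mean peak areas over all heterozygous normals at this SNP."""
    het_normals = calls[(calls["snp_id"] == snp_id)
                        & (calls["tissue"] == "normal")
                        & (calls["call"] == genotype_qc.CALL_HET)]
    if het_normals.empty:
        raise ValueError(f"{snp_id}: no heterozygous normals to impute from")
    subset = peaks[peaks["tissue"] == "normal"].merge(
        het_normals[["sample_id", "snp_id"]], on=["sample_id", "snp_id"])
    return float(subset["area_risk"].mean() / subset["area_nonrisk"].mean())


def call_imbalance(r: float, upper: float = 1.5, lower: float = 0.67) -> str:
    """Imbalance call from one R-ratio; boundary values call no imbalance."""
    if not 0 < lower < 1 < upper:
        raise ValueError("require 0 < lower < 1 < upper")
    if r > upper:
        return CALL_LOSS_RISK
    if r < lower:
        return CALL_LOSS_NONRISK
    return CALL_NO_IMBALANCE


def evaluate_pairs(peaks: pd.DataFrame, calls: pd.DataFrame,
                   pairs: pd.DataFrame | None = None,
                   cutoffs: Cutoffs = DIALECTS["standard"],
                   plot_cap: float = DEFAULT_PLOT_CAP) -> pd.DataFrame:
    """Score every informative pair and call imbalance.

    Returns one row per pair with columns sample_id, snp_id, n_ratio,
    t_ratio, r_ratio, call, imputed_normal, plot_eligible.  Pairs whose
    normal failed and no heterozygous normal exists for imputation are
    dropped with a log entry.
    """
    if pairs is None:
        pairs = genotype_qc.select_het_pairs(calls)
    if pairs.empty:
        return pd.DataFrame(columns=["sample_id", "snp_id", "n_ratio", "t_ratio",
                                     "r_ratio", "call", "imputed_normal",
                                     "plot_eligible"])
    indexed = peaks.set_index(["sample_id", "snp_id", "tissue"])

    imputed_cache: dict[str, float | None] = {}

    def surrogate(snp: str) -> float | None:
        if snp not in imputed_cache:
            try:
                imputed_cache[snp] = impute_normal_ratio(snp, calls, peaks)
            except ValueError:
                imputed_cache[snp] = None
        return imputed_cache[snp]

    rows = []
    for pair in pairs.itertuples(index=False):
        if pair.needs_imputation:
            n_rat = surrogate(pair.snp_id)
            if n_rat is None:
                log.warning("dropping pair (%s, %s): normal failed and no "
                            "heterozygous normal available for imputation",
                            pair.sample_id, pair.snp_id)
                continue
        else:
            normal = indexed.loc[(pair.sample_id, pair.snp_id, "normal")]
            n_rat = allele_ratio(float(normal["area_risk"]),
                                 float(normal["area_nonrisk"]))
        tumor = indexed.loc[(pair.sample_id, pair.snp_id, "tumor")]
        t_rat = allele_ratio(float(tumor["area_risk"]),
                             float(tumor["area_nonrisk"]))
        r = r_ratio(n_rat, t_rat)
        rows.append({
            "sample_id": pair.sample_id,
            "snp_id": pair.snp_id,
            "n_ratio": n_rat,
            "t_ratio": t_rat,
            "r_ratio": r,
            "call": call_imbalance(r, cutoffs.upper, cutoffs.lower),
            "imputed_normal": bool(pair.needs_imputation),
            "plot_eligible": bool(0 < r < math.inf and r <= plot_cap),
        })
    return pd.DataFrame(rows)


def summarize_snp(pair_results: pd.DataFrame, snp_id: str) -> ImbalanceCounts:
    """Count imbalance calls for one SNP."""
    sub = pair_results[pair_results["snp_id"] == snp_id] if not pair_results.empty \
        else pair_results
    if sub.empty:
        return ImbalanceCounts(snp_id, 0, 0, 0)
    return ImbalanceCounts(
        snp_id=snp_id,
        n_het=int(len(sub)),
        n_loss_risk=int((sub["call"] == CALL_LOSS_RISK).sum()),
        n_loss_nonrisk=int((sub["call"] == CALL_LOSS_NONRISK).sum()),
    )


def summarize_all(pair_results: pd.DataFrame,
                  snp_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-SNP imbalance count table (columns snp_id, n_het, n_loss_risk,
    n_loss_nonrisk, n_total_imbalance)."""
    if snp_ids is None:
        snp_ids = sorted(pair_results["snp_id"].unique()) if not pair_results.empty else []
    rows = []
    for snp in snp_ids:
        c = summarize_snp(pair_results, snp)
        rows.append({"snp_id": c.snp_id, "n_het": c.n_het,
                     "n_loss_risk": c.n_loss_risk,
                     "n_loss_nonrisk": c.n_loss_nonrisk,
                     "n_total_imbalance": c.n_total_imbalance})
    return pd.DataFrame(rows, columns=["snp_id", "n_het", "n_loss_risk",
                                       "n_loss_nonrisk", "n_total_imbalance"])


def plot_values(pair_results: pd.DataFrame,
                cap: float = DEFAULT_PLOT_CAP) -> dict[str, np.ndarray]:
    """Plot-ready R-ratio values grouped by call.

    Pairs with R above ``cap``, or whose R-ratio is a sentinel because a
    tumor allele peak was absent, are excluded.
    """
    out: dict[str, np.ndarray] = {}
    for call in (CALL_LOSS_RISK, CALL_LOSS_NONRISK, CALL_NO_IMBALANCE):
        if pair_results.empty:
            out[call] = np.array([])
            continue
        sub = pair_results[pair_results["call"] == call]
        r = sub["r_ratio"].to_numpy(float)
        out[call] = r[(r > 0) & np.isfinite(r) & (r <= cap)]
    return out
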