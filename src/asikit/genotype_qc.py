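"""Genotype calling from allele peak areas and SNP-level quality control.

The quantitative genotyping platform reports one peak area per allele; a
genotype is assigned from the minor-allele fraction of the total signal.  The
het/hom decision band and the detection floor are analysis parameters (the
vendor rule is proprietary): a measurement whose total area falls below the
floor is a failed assay, a measurement whose minor-allele fraction reaches
``het_band`` is heterozygous, anything else is homozygous for the majority
allele.  The default band of 0.15 calls the smallest calibration mixture
(20% minor allele) heterozygous with margin.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

DEFAULT_FLOOR_FRACTION = 0.05
DEFAULT_HET_BAND = 0.15
DEFAULT_MAX_FAILURE_RATE = 0.15
DEFAULT_MAF_FLOOR = 0.20

CALL_HET = "het"
CALL_HOM_RISK = "hom_risk"
CALL_HOM_NONRISK = "hom_nonrisk"
CALL_FAIL = "fail"

CALL_COLUMNS = ["sample_id", "snp_id", "tissue", "call", "n_ratio"]


@dataclasses.dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    snp_id: str
    tissue: str
    call: str
    n_ratio: float  # area_risk / area_nonrisk; nan when the assay failed


@dataclasses.dataclass(frozen=True)
class QcSummary:
    snp_id: str
    n_attempted: int
    n_failed: int
    failure_rate: float
    retained: bool


def call_genotype(area_risk: float, area_nonrisk: float, floor: float,
                  het_band: float = DEFAULT_HET_BAND) -> str:
    """Call one measurement: fail below the detection floor, het when each
    allele carries at least ``het_band`` of the total signal, else hom."""
    if not floor > 0:
        raise ValueError("floor must be positive")
    if not 0 < het_band < 0.5:
        raise ValueError("het_band must lie in (0, 0.5)")
    total = area_risk + area_nonrisk
    if total < floor:
        return CALL_FAIL
    minor = min(area_risk, area_nonrisk) / total
    if minor >= het_band:
        return CALL_HET
    return CALL_HOM_RISK if area_risk >= area_nonrisk else CALL_HOM_NONRISK


def detection_floor(peaks: pd.DataFrame,
                    floor_fraction: float = DEFAULT_FLOOR_FRACTION) -> float:
    """Detection floor as a fraction of the cohort-median non-zero total area."""
    totals = peaks["area_risk"].to_numpy() + peaks["area_nonrisk"].to_numpy()
    positive = totals[totals > 0]
    if positive.size == 0:
        raise ValueError("no measurement with positive total area")
    return floor_fraction * float(np.median(positive))


def call_genotypes(peaks: pd.DataFrame, *, floor: float | None = None,
                   floor_fraction: float = DEFAULT_FLOOR_FRACTION,
                   het_band: float = DEFAULT_HET_BAND) -> pd.DataFrame:
    """Vectorised genotype calling over a whole peak table.

    Returns a frame with columns sample_id, snp_id, tissue, call, n_ratio.
    ``n_ratio`` is area_risk/area_nonrisk (+inf for a hom-risk measurement
    with zero non-risk area, nan for failed assays).
    """
    if floor is None:
        floor = detection_floor(peaks, floor_fraction)
    if not 0 < het_band < 0.5:
        raise ValueError("het_band must lie in (0, 0.5)")
    risk = peaks["area_risk"].to_numpy(float)
    nonrisk = peaks["area_nonrisk"].to_numpy(float)
    total = risk + nonrisk
    fail = total < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        minor = np.where(total > 0, np.minimum(risk, nonrisk) / np.where(total > 0, total, 1.0), 0.0)
        n_ratio = np.where(nonrisk > 0, risk / np.where(nonrisk > 0, nonrisk, 1.0), np.inf)
    call = np.where(risk >= nonrisk, CALL_HOM_RISK, CALL_HOM_NONRISK)
    call = np.where(minor >= het_band, CALL_HET, call)
    call = np.where(fail, CALL_FAIL, call)
    n_ratio = np.where(fail, np.nan, n_ratio)
    return pd.DataFrame({
        "sample_id": peaks["sample_id"].to_numpy(),
        "snp_id": peaks["snp_id"].to_numpy(),
        "tissue": peaks["tissue"].to_numpy(),
        "call": call,
        "n_ratio": n_ratio,
    })


def qc_by_snp(calls: pd.DataFrame,
              max_failure_rate: float = DEFAULT_MAX_FAILURE_RATE) -> pd.DataFrame:
    """Per-SNP assay failure rates, pooled over both tissues.

    A SNP is retained when its failure rate does not exceed
    ``max_failure_rate`` (strictly greater excludes, the boundary retains).
    """
    if calls.empty:
        raise ValueError("no genotype calls to summarise")
    grouped = calls.groupby("snp_id", sort=True)["call"]
    n_attempted = grouped.size()
    n_failed = grouped.apply(lambda s: int((s == CALL_FAIL).sum()))
    rate = n_failed / n_attempted
    return pd.DataFrame({
        "snp_id": n_attempted.index,
        "n_attempted": n_attempted.to_numpy(),
        "n_failed": n_failed.to_numpy(),
        "failure_rate": rate.to_numpy(),
        "retained": (rate <= max_failure_rate).to_numpy(),
    }).reset_index(drop=True)


def screen_panel(panel: pd.DataFrame,
                 maf_floor: float = DEFAULT_MAF_FLOOR) -> pd.DataFrame:
    """Pre-genotyping panel screen: keep SNPs with maf strictly above the
    floor, or carrying the explicit low-frequency exception flag."""
    keep = (panel["maf"] > maf_floor) | panel["maf_exception"].astype(bool)
    return panel[keep].reset_index(drop=True)


def select_het_pairs(calls: pd.DataFrame) -> pd.DataFrame:
    """Select informative normal/tumor pairs per sample and SNP.

    A pair is informative when the normal is heterozygous and the tumor assay
    did not fail, or — the imputation route — when the normal assay failed but
    the tumor is heterozygous.  Returns columns sample_id, snp_id,
    needs_imputation.
    """
    wide = calls.pivot_table(index=["sample_id", "snp_id"], columns="tissue",
                             values="call", aggfunc="first", observed=True)
    for tissue in ("normal", "tumor"):
        if tissue not in wide.columns:
            wide[tissue] = np.nan
    normal = wide["normal"]
    tumor = wide["tumor"]
    direct = (normal == CALL_HET) & tumor.notna() & (tumor != CALL_FAIL)
    imputed = (normal == CALL_FAIL) & (tumor == CALL_HET)
    selected = wide[direct | imputed].index.to_frame(index=False)
    selected["needs_imputation"] = imputed[direct | imputed].to_numpy()
    return selected.reset_index(drop=True)
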