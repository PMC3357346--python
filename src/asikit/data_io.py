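"""Readers, writers and report rendering for the study's tab-separated tables.

All on-disk tables are UTF-8, tab-separated, one header row; lines starting
with ``#`` are comments.  In-memory tables are :class:`pandas.DataFrame`
objects with the column layouts documented per reader.  Allele orientation is
fixed at parse time: the ``area_risk`` / ``area_nonrisk`` columns always refer
to the GWAS risk and non-risk allele of the panel entry, so no strand or
column-order ambiguity survives into the analysis.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
TISSUES = ("normal", "tumor")
STAGES = ("I", "II", "III", "IV")
SEXES = ("female", "male")

PANEL_COLUMNS = ["snp_id", "risk_allele", "nonrisk_allele", "maf",
                 "locus_label", "maf_exception"]
PEAK_COLUMNS = ["sample_id", "snp_id", "tissue", "area_risk", "area_nonrisk"]
CLINICAL_COLUMNS = ["sample_id", "age", "sex", "stage"]
STUDY_COUNT_COLUMNS = ["study_id", "snp_id", "n_het", "n_loss_risk",
                       "n_loss_nonrisk"]


class TableValidationError(ValueError):
    """A table violates a schema or domain invariant."""


@dataclasses.dataclass(frozen=True)
class SnpPanelEntry:
    """One SNP of the assay panel.

    ``maf_exception`` marks a SNP admitted below the minor-allele-frequency
    floor (the panel's low-frequency exception).
    """

    snp_id: str
    risk_allele: str
    nonrisk_allele: str
    maf: float
    locus_label: str = ""
    maf_exception: bool = False

    def __post_init__(self) -> None:
        if self.risk_allele not in VALID_BASES or self.nonrisk_allele not in VALID_BASES:
            raise TableValidationError(
                f"{self.snp_id}: alleles must be one of A/C/G/T, got "
                f"{self.risk_allele!r}/{self.nonrisk_allele!r}")
        if self.risk_allele == self.nonrisk_allele:
            raise TableValidationError(f"{self.snp_id}: risk and non-risk allele identical")
        if not 0.0 <= self.maf <= 0.5:
            raise TableValidationError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")


@dataclasses.dataclass(frozen=True)
class PeakMeasurement:
    """One allele-peak-area observation for (sample, SNP, tissue).

    Areas are in arbitrary mass-spectrometry units; both areas zero encodes
    an assay failure.
    """

    sample_id: str
    snp_id: str
    tissue: str
    area_risk: float
    area_nonrisk: float

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise TableValidationError(f"tissue must be normal/tumor, got {self.tissue!r}")
        if self.area_risk < 0 or self.area_nonrisk < 0:
            raise TableValidationError(
                f"({self.sample_id}, {self.snp_id}, {self.tissue}): negative peak area")


@dataclasses.dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    age_at_diagnosis: float | None = None
    sex: str | None = None
    tnm_stage: str | None = None

    def __post_init__(self) -> None:
        if self.age_at_diagnosis is not None and not self.age_at_diagnosis > 0:
            raise TableValidationError(f"{self.sample_id}: age must be positive")
        if self.sex is not None and self.sex not in SEXES:
            raise TableValidationError(f"{self.sample_id}: sex {self.sex!r} invalid")
        if self.tnm_stage is not None and self.tnm_stage not in STAGES:
            raise TableValidationError(f"{self.sample_id}: stage {self.tnm_stage!r} invalid")


@dataclasses.dataclass(frozen=True)
class StudyCounts:
    """Per-study, per-SNP imbalance counts used for cross-study pooling."""

    study_id: str
    snp_id: str
    n_het: int
    n_loss_risk: int
    n_loss_nonrisk: int

    def __post_init__(self) -> None:
        if min(self.n_het, self.n_loss_risk, self.n_loss_nonrisk) < 0:
            raise TableValidationError(f"{self.study_id}/{self.snp_id}: negative count")
        if self.n_loss_risk + self.n_loss_nonrisk > self.n_het:
            raise TableValidationError(
                f"{self.study_id}/{self.snp_id}: losses exceed heterozygote count")


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False, na_values=[""])
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing columns {missing}")
    return df[list(columns)]


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a SNP panel table.

    Columns: snp_id, risk_allele, nonrisk_allele, maf, locus_label,
    maf_exception.  Raises :class:`TableValidationError` on duplicate SNP ids,
    invalid alleles or maf outside [0, 0.5].
    """
    df = _read_tsv(path, PANEL_COLUMNS)
    if df.empty:
        log.warning("panel %s is empty (header only)", path)
        return df.assign(maf=pd.Series(dtype=float),
                         maf_exception=pd.Series(dtype=bool))
    df["maf"] = df["maf"].astype(float)
    df["locus_label"] = df["locus_label"].fillna("")
    df["maf_exception"] = (
        df["maf_exception"].fillna("false").str.lower()
        .map({"true": True, "false": False, "1": True, "0": False})
    )
    if df["maf_exception"].isna().any():
        raise TableValidationError(f"{path}: maf_exception must be true/false")
    if df["snp_id"].duplicated().any():
        dups = sorted(df.loc[df["snp_id"].duplicated(), "snp_id"])
        raise TableValidationError(f"{path}: duplicate snp_id {dups}")
    for row in df.itertuples(index=False):
        SnpPanelEntry(row.snp_id, row.risk_allele, row.nonrisk_allele,
                      row.maf, row.locus_label, row.maf_exception)
    return df


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_peak_table(path: str | Path, panel: pd.DataFrame) -> pd.DataFrame:
    """Read a peak-area table and validate it against ``panel``.

    Columns: sample_id, snp_id, tissue, area_risk, area_nonrisk.  Row order is
    preserved.  Rejects negative areas (naming the offending row), duplicate
    (sample, snp, tissue) keys and SNP ids absent from the panel.
    """
    df = _read_tsv(path, PEAK_COLUMNS)
    for col in ("area_risk", "area_nonrisk"):
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise TableValidationError(f"{path}: non-numeric {col}: {exc}") from exc
        neg = df.index[df[col] < 0]
        if len(neg):
            raise TableValidationError(
                f"{path}: negative {col} at data row {neg[0] + 1}")
    bad_tissue = ~df["tissue"].isin(TISSUES)
    if bad_tissue.any():
        raise TableValidationError(
            f"{path}: invalid tissue at data row {df.index[bad_tissue][0] + 1}")
    known = set(panel["snp_id"])
    unknown = sorted(set(df["snp_id"]) - known)
    if unknown:
        raise TableValidationError(f"{path}: snp_id not in panel: {unknown}")
    key = df[["sample_id", "snp_id", "tissue"]]
    if key.duplicated().any():
        first = key[key.duplicated()].iloc[0]
        raise TableValidationError(
            f"{path}: duplicate measurement for ({first.sample_id}, "
            f"{first.snp_id}, {first.tissue})")
    return df


def write_peak_table(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[PEAK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical covariate table (missing fields are empty cells)."""
    df = _read_tsv(path, CLINICAL_COLUMNS)
    df["age"] = df["age"].astype(float)
    if (df["age"] <= 0).any():
        raise TableValidationError(f"{path}: non-positive age")
    bad = df["sex"].notna() & ~df["sex"].isin(SEXES)
    if bad.any():
        raise TableValidationError(f"{path}: invalid sex value")
    bad = df["stage"].notna() & ~df["stage"].isin(STAGES)
    if bad.any():
        raise TableValidationError(f"{path}: invalid stage value")
    if df["sample_id"].duplicated().any():
        raise TableValidationError(f"{path}: duplicate sample_id")
    return df


def read_study_counts(path: str | Path) -> pd.DataFrame:
    """Read external per-study imbalance count tables for meta-pooling."""
    df = _read_tsv(path, STUDY_COUNT_COLUMNS)
    for col in ("n_het", "n_loss_risk", "n_loss_nonrisk"):
        df[col] = df[col].astype(int)
    for row in df.itertuples(index=False):
        StudyCounts(row.study_id, row.snp_id, row.n_het,
                    row.n_loss_risk, row.n_loss_nonrisk)
    if df[["study_id", "snp_id"]].duplicated().any():
        raise TableValidationError(f"{path}: duplicate (study_id, snp_id)")
    return df


def write_study_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts[STUDY_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


# --- publication-style rendering -------------------------------------------

def format_percent(numerator: int, denominator: int) -> str:
    """Whole-percent rendering, half away from zero: (6, 67) -> '9%'."""
    pct = math.floor(100.0 * numerator / denominator + 0.5)
    return f"{pct}%"


def format_count(numerator: int, denominator: int) -> str:
    """'a (c%)' rendering of a count over its heterozygote total."""
    return f"{numerator} ({format_percent(numerator, denominator)})"


def format_fraction(numerator: int, denominator: int) -> str:
    """'a/b (c%)' rendering, e.g. (20, 67) -> '20/67 (30%)'."""
    return f"{numerator}/{denominator} ({format_percent(numerator, denominator)})"


def format_p(p: float) -> str:
    """P-value rendering: two decimals at or above 0.01, else 3 significant
    figures in scientific notation (0.0735 -> '0.07', 2.94e-5 -> '2.94e-05')."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if round(p, 2) >= 0.01:
        return f"{round(p, 2):.2f}"
    return f"{p:.2e}"


def write_report(results: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Write a per-SNP imbalance report in the publication column layout.

    ``results`` needs columns snp_id, risk_allele, nonrisk_allele, n_het,
    n_loss_risk, n_loss_nonrisk, p, p_adjusted.  Returns the rendered frame.
    """
    rows = []
    for r in results.itertuples(index=False):
        total = r.n_loss_risk + r.n_loss_nonrisk
        rows.append({
            "snp_id": r.snp_id,
            "risk_allele": r.risk_allele,
            "nonrisk_allele": r.nonrisk_allele,
            "risk_allele_lost": format_count(r.n_loss_risk, r.n_het),
            "nonrisk_allele_lost": format_count(r.n_loss_nonrisk, r.n_het),
            "total_imbalance": format_fraction(total, r.n_het),
            "p": format_p(r.p),
            "p_adjusted": format_p(r.p_adjusted),
        })
    rendered = pd.DataFrame(rows)
    rendered.to_csv(path, sep="\t", index=False)
    return rendered
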