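"""Mixture standard-curve verification of quantitative genotyping.

Sensitivity of peak-area genotyping to allelic imbalance is verified by
genotyping mixtures of two homozygous DNAs at known proportions and fitting
ln(N-ratio) against the percentage of allele 1 by ordinary least squares.
For an assay with perfectly proportional peak areas the curve is the logit
line ln((100 - p)/p): its OLS fit over the standard five-point design
{20, 40, 50, 60, 80} has slope -0.0456 and intercept 2.2822.  The 0% and
100% mixtures have no finite log-ratio; they stay in the design as
homozygote controls but are excluded from fits.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_DESIGN = (0.0, 20.0, 40.0, 50.0, 60.0, 80.0, 100.0)

# Pass tolerances calibrated by Monte-Carlo so that noiseless data passes
# with wide margin and ~5% multiplicative peak-area noise passes in >=95%
# of runs; they are analysis defaults, not instrument specifications.
DEFAULT_SLOPE_TOL = 0.005
DEFAULT_INTERCEPT_TOL = 0.25
DEFAULT_MIN_R_SQUARED = 0.95


@dataclasses.dataclass(frozen=True)
class MixturePoint:
    """One mixture observation: percent allele 1 and its measured N-ratio."""

    pct_allele1: float
    n_ratio: float

    @property
    def log_n_ratio(self) -> float:
        return math.log(self.n_ratio)

    @property
    def fit_eligible(self) -> bool:
        return 0.0 < self.pct_allele1 < 100.0 and 0.0 < self.n_ratio < math.inf


@dataclasses.dataclass(frozen=True)
class StandardCurve:
    slope: float       # per percent allele 1
    intercept: float
    r_squared: float
    n_points: int

    def predict(self, pct_allele1: float) -> float:
        return self.slope * pct_allele1 + self.intercept


@dataclasses.dataclass(frozen=True)
class AssayAssessment:
    slope_deviation: float
    intercept_deviation: float
    r_squared: float
    passed: bool


def design_mixtures() -> list[float]:
    """The standard mixture design: 0, 20, 40, 50, 60, 80 and 100 percent
    contributions of allele 1."""
    return list(DEFAULT_DESIGN)


def fit_eligible(percents: Iterable[float]) -> list[float]:
    """Design points with a finite log allele ratio (endpoints excluded)."""
    return [p for p in percents if 0.0 < p < 100.0]


def ideal_log_ratio(pct_allele1: float) -> float:
    """Expected ln(N-ratio) of a perfectly proportional assay at a mixture
    containing ``pct_allele1`` percent of allele 1: ln((100 - p)/p)."""
    if not 0.0 < pct_allele1 < 100.0:
        raise ValueError(f"log ratio undefined at {pct_allele1}% (pure homozygote)")
    return math.log((100.0 - pct_allele1) / pct_allele1)


def ideal_points(design: Iterable[float] = DEFAULT_DESIGN) -> list[MixturePoint]:
    """Noiseless mixture points of the ideal curve over the fit-eligible
    part of a design."""
    return [MixturePoint(p, math.exp(ideal_log_ratio(p)))
            for p in fit_eligible(design)]


def fit_standard_curve(points: Sequence[MixturePoint]) -> StandardCurve:
    """Ordinary least squares of ln(N-ratio) on percent allele 1.

    Endpoint mixtures (0/100%, or zero/infinite ratios) are dropped; at
    least two eligible points with distinct percentages are required.
    """
    eligible = [pt for pt in points if pt.fit_eligible]
    x = np.array([pt.pct_allele1 for pt in eligible])
    y = np.array([pt.log_n_ratio for pt in eligible])
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise ValueError("need at least two fit-eligible points with distinct percents")
    fit = stats.linregress(x, y)
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue) ** 2, n_points=len(x))


def ideal_curve(design: Iterable[float] = DEFAULT_DESIGN) -> StandardCurve:
    """The ideal standard curve: OLS fit to the noiseless logit points."""
    return fit_standard_curve(ideal_points(design))


def assess_assay(curve: StandardCurve, ideal: StandardCurve | None = None,
                 slope_tol: float = DEFAULT_SLOPE_TOL,
                 intercept_tol: float = DEFAULT_INTERCEPT_TOL,
                 min_r_squared: float = DEFAULT_MIN_R_SQUARED) -> AssayAssessment:
    """Compare a fitted curve against the ideal curve on the same design."""
    if ideal is None:
        ideal = ideal_curve()
    ds = abs(curve.slope - ideal.slope)
    di = abs(curve.intercept - ideal.intercept)
    passed = (ds <= slope_tol and di <= intercept_tol
              and curve.r_squared >= min_r_squared)
    return AssayAssessment(ds, di, curve.r_squared, passed)


def read_mixture_table(path, snp_id: str | None = None) -> list[MixturePoint]:
    """Read mixture measurements (columns snp_id, pct_allele1, area_allele1,
    area_allele2) into points for one SNP."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if snp_id is not None:
        df = df[df["snp_id"] == snp_id]
    points = []
    for r in df.itertuples(index=False):
        ratio = math.inf if r.area_allele2 == 0 else r.area_allele1 / r.area_allele2
        points.append(MixturePoint(float(r.pct_allele1), float(ratio)))
    return points


def write_curve_report(curves: dict[str, tuple[StandardCurve, AssayAssessment]],
                       path) -> pd.DataFrame:
    rows = [{"snp_id": snp, "slope": c.slope, "intercept": c.intercept,
             "r2": c.r_squared, "passed": a.passed}
            for snp, (c, a) in curves.items()]
    df = pd.DataFrame(rows, columns=["snp_id", "slope", "intercept", "r2", "passed"])
    df.to_csv(path, sep="\t", index=False)
    return df
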