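"""Shared fixtures: published per-SNP count tables and small synthetic cohorts."""

import pandas as pd
import pytest

from asikit import synthetic_data

# Discovery-cohort imbalance counts per SNP:
# (snp_id, risk, nonrisk, n_loss_risk, n_loss_nonrisk, n_het, printed p)
DISCOVERY_ROWS = [
    ("rs16892766", "C", "A", 6, 1, 27, "0.06"),
    ("rs6983267", "G", "T", 6, 14, 67, "0.07"),
    ("rs7136702", "T", "C", 12, 5, 75, "0.09"),
    ("rs10936599", "C", "T", 6, 2, 49, "0.16"),
    ("rs3802842", "C", "A", 9, 4, 75, "0.17"),
    ("rs961253", "A", "C", 11, 6, 71, "0.23"),
    ("rs6687758", "G", "A", 8, 4, 55, "0.25"),
    ("rs4779584", "T", "C", 9, 14, 53, "0.30"),
    ("rs4939827", "T", "C", 19, 15, 78, "0.49"),
    ("rs7014346", "A", "G", 6, 4, 82, "0.53"),
    ("rs9929218", "G", "A", 2, 1, 62, "0.56"),
    ("rs10411210", "C", "T", 4, 3, 35, "0.71"),
    ("rs4444235", "C", "T", 8, 7, 81, "0.80"),
    ("rs719725", "A", "C", 8, 9, 65, "0.81"),
    ("rs6691170", "T", "G", 5, 5, 79, "1.00"),
    ("rs11169552", "C", "T", 1, 1, 84, "1.00"),
]

# Validation-cohort counts for the three screened SNPs, with printed p.
VALIDATION_ROWS = [
    ("rs7136702", "T", "C", 6, 8, 133, "0.59"),
    ("rs16892766", "C", "A", 3, 3, 38, "1.00"),
    ("rs6983267", "G", "T", 9, 19, 125, "0.06"),
]

# External-study loss counts for the seven meta-analysis SNPs.
PUBLISHED_STUDY_ROWS = [
    ("published", "rs6983267", 466, 34, 67),
    ("published", "rs961253", 88, 16, 11),
    ("published", "rs3802842", 89, 5, 4),
    ("published", "rs10411210", 174, 5, 10),
    ("published", "rs4444235", 90, 10, 7),
    ("published", "rs4779584", 87, 9, 8),
    ("published", "rs9929218", 90, 4, 6),
]
META_SNPS = [row[1] for row in PUBLISHED_STUDY_ROWS]

# Printed unadjusted meta p-values per SNP.
META_PRINTED_P = {
    "rs6983267": 2.94e-5, "rs961253": 0.13, "rs3802842": 0.20,
    "rs10411210": 0.39, "rs4444235": 0.48, "rs4779584": 0.53,
    "rs9929218": 0.78,
}


def _counts_frame(rows):
    return pd.DataFrame(
        [(snp, het, a, b, a + b) for snp, _, _, a, b, het, _ in rows],
        columns=["snp_id", "n_het", "n_loss_risk", "n_loss_nonrisk",
                 "n_total_imbalance"])


@pytest.fixture(scope="session")
def discovery_counts():
    return _counts_frame(DISCOVERY_ROWS)


@pytest.fixture(scope="session")
def validation_counts():
    return _counts_frame(VALIDATION_ROWS)


@pytest.fixture(scope="session")
def published_study_counts():
    return pd.DataFrame(PUBLISHED_STUDY_ROWS,
                        columns=["study_id", "snp_id", "n_het",
                                 "n_loss_risk", "n_loss_nonrisk"])


@pytest.fixture(scope="session")
def panel():
    return synthetic_data.default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest deterministic cohort reused across integration tests."""
    cfg = synthetic_data.SimConfig(n_pairs=60, seed=42)
    peaks, truth = synthetic_data.simulate_cohort(cfg)
    return cfg, peaks, truth
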