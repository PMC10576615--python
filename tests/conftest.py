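"""Shared fixtures: simulated cohorts at the scales the checks need.

Session-scoped so the expensive simulations and association scans run once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from remnantmr import gwas
from remnantmr.config import CohortParams
from remnantmr.lipids import derive_lipid_columns
from remnantmr.synthetic import Cohort, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="TG above the Sampson")


@dataclass
class ScannedCohort:
    cohort: Cohort
    subjects: pd.DataFrame          # with derived lipid columns
    covariates: np.ndarray
    scans: dict[str, pd.DataFrame]
    outcome_scan: pd.DataFrame

    @property
    def params(self) -> CohortParams:
        return self.cohort.params


def _scan_cohort(params: CohortParams) -> ScannedCohort:
    cohort = simulate_cohort(params)
    subjects = derive_lipid_columns(cohort.subjects)
    covs = gwas.covariate_matrix(subjects)
    scans = {
        trait: gwas.assoc_scan(cohort.genotypes, subjects[col], covs, trait)
        for trait, col in [
            ("ldl_c", "ldl_c_direct"),
            ("trl_remnant_c", "trl_remnant_c"),
            ("tg", "tg"),
            ("apob", "apob"),
            ("lpa", "lpa"),
        ]
    }
    combined = (
        (subjects["prevalent_ascvd"] == 1) | (subjects["incident_event"] == 1)
    ).astype(float)
    outcome = gwas.binary_assoc_scan(cohort.genotypes, combined, covs)
    return ScannedCohort(cohort, subjects, covs, scans, outcome)


@pytest.fixture(scope="session")
def small_cohort() -> ScannedCohort:
    """Desk-scale cohort for fast structural checks."""
    return _scan_cohort(CohortParams(n_subjects=4000, n_variants=150, seed=42))


@pytest.fixture(scope="session")
def big_cohort() -> ScannedCohort:
    """Large cohort (n=50k) for classification-recovery and score checks."""
    return _scan_cohort(CohortParams(n_subjects=50_000, n_variants=300, seed=7))


@pytest.fixture(scope="session")
def ld_free_cohort() -> ScannedCohort:
    """Independent-variant cohort for checks whose clean statement assumes
    no LD (score calibration, estimator coverage)."""
    return _scan_cohort(CohortParams(n_subjects=30_000, n_variants=150, ld_rho=0.0, seed=21))


@pytest.fixture()
def rng() -> np.random.Generator:
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(20230626)
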