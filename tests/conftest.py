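"""Shared fixtures: simulated cohorts are expensive, so they are built
once per session and reused across unit and acceptance tests."""

from pathlib import Path

import numpy as np
import pytest

from tonicephys.ap_features import cohort_feature_matrices, extract_cell_features
from tonicephys.synthetic_data import CohortConfig, simulate_cohort

DATA_DIR = Path(__file__).parent / "data"

COHORT_SEED = 20260401


@pytest.fixture(scope="session")
def default_cohort():
    """100 cells, all five archetypes in equal proportion, default
    within-archetype jitter (the standard clustering test bed)."""
    records, patients = simulate_cohort(n_cells=100, seed=COHORT_SEED)
    return records, patients


@pytest.fixture(scope="session")
def default_cohort_features(default_cohort):
    records, _ = default_cohort
    feats = [extract_cell_features(r) for r in records]
    mats, report = cohort_feature_matrices(records, feats_list=feats)
    return feats, mats, report


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """50 cells with zero recording noise for exact feature recovery."""
    cfg = CohortConfig(sigma_v=0.0)
    records, _ = simulate_cohort(cfg, n_cells=50, seed=COHORT_SEED + 1)
    return records


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def patients_csv():
    return DATA_DIR / "patients_table1.csv"
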