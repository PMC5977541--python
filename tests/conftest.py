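"""Shared fixtures: synthetic cohorts and their cross-validation results.

The heavy cohorts are session-scoped so that the effect-recovery, null,
and anti-leakage checks all reuse one feature extraction.
"""

import numpy as np
import pytest

from nucmorph.classify import ClassifierSpec, CVConfig, cross_validate
from nucmorph.pipeline import (
    build_experiment,
    extract_feature_table,
    modeling_matrix,
)
from nucmorph.synthetic import (
    SyntheticCohortConfig,
    generate_cohort,
    null_config,
)

STRONG_SEED = 20180530
NULL_SEED = 20180531


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong-effect cohort: 30 patients/class, 10 patches each, default
    low/high phenotypes."""
    cfg = SyntheticCohortConfig(
        n_patients_per_class=30, patches_per_patient=10, seed=STRONG_SEED
    )
    cases = generate_cohort(cfg)
    table = extract_feature_table(cases)
    return cases, table


@pytest.fixture(scope="session")
def strong_cv(strong_cohort):
    """10 iterations of grouped 3-fold CV (ranksum + random forest) on the
    strong-effect cohort, low vs high ODx."""
    cases, table = strong_cohort
    _, labels = build_experiment(cases, "LvsH")
    X, y, pids, names = modeling_matrix(table, labels)
    result = cross_validate(
        X, y, pids, names,
        ClassifierSpec(kind="random_forest", seed=STRONG_SEED),
        CVConfig(n_iterations=10, ranker="ranksum", seed=STRONG_SEED),
    )
    return result, (X, y, pids, names)


def mean_null_auc(X, y, pids, names, seed, n_assignments=4, n_iterations=5):
    """Mean cross-validated AUC over seeded patient-level class assignments.

    Under a null cohort (or permuted labels) every patient-level
    assignment is an equally valid draw from the null, so averaging over
    several halves the sampling noise of a single-assignment AUC.
    """
    rng = np.random.default_rng(seed)
    patients = np.unique(pids)
    base = np.array([int(y[pids == p][0]) for p in patients])
    aucs = []
    for k in range(n_assignments):
        assigned = base if k == 0 else rng.permutation(base)
        label_map = dict(zip(patients, assigned))
        y_k = np.array([label_map[p] for p in pids])
        result = cross_validate(
            X, y_k, pids, names,
            ClassifierSpec(kind="random_forest", seed=seed + k),
            CVConfig(n_iterations=n_iterations, ranker="ranksum", seed=seed + k),
        )
        aucs.append(result.auc_mean)
    return float(np.mean(aucs))


@pytest.fixture(scope="session")
def null_cv():
    """Null cohort (identical phenotypes): mean CV AUC over seeded
    patient-level class assignments."""
    cfg = null_config(n_patients_per_class=20, patches_per_patient=3, seed=NULL_SEED)
    cases = generate_cohort(cfg)
    table = extract_feature_table(cases)
    _, labels = build_experiment(cases, "LvsH")
    X, y, pids, names = modeling_matrix(table, labels)
    return mean_null_auc(X, y, pids, names, seed=NULL_SEED)


@pytest.fixture(scope="session")
def small_cohort():
    """A small strong-effect cohort for plumbing-level pipeline tests."""
    cfg = SyntheticCohortConfig(
        n_patients_per_class=6, patches_per_patient=2, patch_size_px=384, seed=42
    )
    cases = generate_cohort(cfg)
    table = extract_feature_table(cases)
    return cases, table


@pytest.fixture
def rng():
    return np.random.default_rng(0)
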