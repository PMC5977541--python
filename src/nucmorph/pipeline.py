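"""Cohort-level orchestration: risk categorization rules, case exclusion,
the four classification experiments, feature-table assembly, the
compartment-separation ablation, and frozen-model external validation.

Oncotype DX recurrence scores (0-100) are bucketed low (<= 17),
intermediate (18-30), high (>= 31). Modified Bloom-Richardson grades
(3-9) are bucketed low (4-5), moderate (6-7), high (8-9); a grade of 3
falls below the buckets and maps to low (logged). Cases whose ODx
category and mBR bucket sit at opposite extremes are excluded before any
experiment. The positive label is always the higher-risk side, so an
AUC above 0.5 means risk-concordant scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nucmorph.classify import (
    ClassifierSpec,
    CVConfig,
    cross_validate,
    score_patches,
    POSITIVE_SCORE_THRESHOLD,
)
from nucmorph.ranking import rank_features
from nucmorph.shape import patch_feature_names, patch_feature_vector
from nucmorph.types import PatientCase
from nucmorph.voting import optimal_threshold, patch_fraction_positive, voting_accuracy

logger = logging.getLogger(__name__)

ODX_LOW_MAX = 17
ODX_INTERMEDIATE_MAX = 30
TASKS = ("LLvsHH", "LvsH", "LvsIH", "LIvsH")


def categorize_odx(score: int) -> str:
    """ODx category: <= 17 low, 18-30 intermediate, >= 31 high."""
    if not (0 <= score <= 100):
        raise ValueError(f"ODx score {score} outside 0-100")
    if score <= ODX_LOW_MAX:
        return "low"
    if score <= ODX_INTERMEDIATE_MAX:
        return "intermediate"
    return "high"


def categorize_mbr(score: int) -> str:
    """mBR bucket: 4-5 low, 6-7 moderate, 8-9 high; 3 maps to low."""
    if not (3 <= score <= 9):
        raise ValueError(f"mBR score {score} outside 3-9")
    if score == 3:
        logger.info("mBR score 3 is below the buckets; mapped to low")
        return "low"
    if score <= 5:
        return "low"
    if score <= 7:
        return "moderate"
    return "high"


def apply_extreme_conflict_exclusion(
    cases: list[PatientCase],
) -> tuple[list[PatientCase], list[str]]:
    """Drop cases with (mBR low, ODx high) or (mBR high, ODx low)."""
    kept, log = [], []
    for case in cases:
        if case.mbr_category == "low" and case.odx_category == "high":
            log.append(f"{case.patient_id}: low mBR with high ODx")
        elif case.mbr_category == "high" and case.odx_category == "low":
            log.append(f"{case.patient_id}: high mBR with low ODx")
        else:
            kept.append(case)
    return kept, log


def build_experiment(
    cases: list[PatientCase], task: str
) -> tuple[list[PatientCase], dict[str, int]]:
    """Select cases and assign binary labels for one experiment.

    LLvsHH: only (ODx low, mBR low) vs (ODx high, mBR high);
    LvsH: ODx low vs high (intermediates excluded);
    LvsIH: all cases, positive = {intermediate, high};
    LIvsH: all cases, positive = {high}.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    selected, labels = [], {}
    for case in cases:
        odx = case.odx_category
        if task == "LLvsHH":
            if odx == "low" and case.mbr_category == "low":
                selected.append(case)
                labels[case.patient_id] = 0
            elif odx == "high" and case.mbr_category == "high":
                selected.append(case)
                labels[case.patient_id] = 1
        elif task == "LvsH":
            if odx in ("low", "high"):
                selected.append(case)
                labels[case.patient_id] = int(odx == "high")
        elif task == "LvsIH":
            selected.append(case)
            labels[case.patient_id] = int(odx in ("intermediate", "high"))
        else:  # LIvsH
            selected.append(case)
            labels[case.patient_id] = int(odx == "high")
    present = set(labels.values())
    if present != {0, 1}:
        raise ValueError(f"task {task} yields a single class: {present}")
    return selected, labels


# ---------------------------------------------------------------------------
# Feature-table assembly
# ---------------------------------------------------------------------------

def extract_feature_table(
    cases: list[PatientCase], mode: str = "separated", min_nuclei: int = 5
) -> pd.DataFrame:
    """Per-patch feature table: patient_id, patch_id, excluded flag, then
    the catalog columns (432 separated / 216 pooled)."""
    names = patch_feature_names(mode)
    rows = []
    for case in cases:
        for patch in case.patches:
            vec, excluded = patch_feature_vector(patch, mode=mode, min_nuclei=min_nuclei)
            rows.append(
                {"patient_id": case.patient_id, "patch_id": patch.patch_id,
                 "excluded": excluded, **dict(zip(names, vec))}
            )
    return pd.DataFrame(rows)


def modeling_matrix(
    table: pd.DataFrame, labels: dict[str, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Drop excluded patches and patients outside the experiment; return
    (X, y, patient_ids, feature_names)."""
    meta_cols = ("patient_id", "patch_id", "excluded")
    names = [c for c in table.columns if c not in meta_cols]
    sub = table[~table["excluded"] & table["patient_id"].isin(labels)]
    X = sub[names].to_numpy(dtype=float)
    y = np.array([labels[p] for p in sub["patient_id"]])
    return X, y, sub["patient_id"].to_numpy(), names


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    tasks: tuple = TASKS
    rankers: tuple = ("ranksum", "pca_vip", "mrmr_mid", "mrmr_miq")
    classifiers: tuple = ("random_forest", "neural_net", "svm", "lda")
    n_iterations: int = 100
    k_folds: int = 3
    n_top_features: int = 10
    seed: int = 0


def run_experiment(
    cases: list[PatientCase],
    table: pd.DataFrame,
    config: ExperimentConfig = ExperimentConfig(),
) -> dict:
    """Run the (task x ranker x classifier) grid and report CV AUC, voting
    accuracy, and selected features per cell."""
    cases, exclusion_log = apply_extreme_conflict_exclusion(cases)
    report: dict = {"exclusions": exclusion_log, "cells": {}}
    for task in config.tasks:
        selected, labels = build_experiment(cases, task)
        X, y, pids, names = modeling_matrix(table, labels)
        for ranker in config.rankers:
            for kind in config.classifiers:
                cv = CVConfig(
                    k_folds=config.k_folds,
                    n_iterations=config.n_iterations,
                    n_top_features=config.n_top_features,
                    ranker=ranker,
                    seed=config.seed,
                )
                result = cross_validate(
                    X, y, pids, names, ClassifierSpec(kind=kind, seed=config.seed), cv
                )
                report["cells"][f"{task}|{ranker}|{kind}"] = {
                    "task": task,
                    "ranker": ranker,
                    "classifier": kind,
                    "n_patients": len(selected),
                    "n_patches": len(X),
                    "auc_mean": result.auc_mean,
                    "auc_std": result.auc_std,
                    "voting_accuracy_mean": result.voting_accuracy_mean,
                    "top_features": result.selected_features[0][0],
                }
    return report


def compartment_ablation(
    cases: list[PatientCase],
    table_separated: pd.DataFrame,
    table_pooled: pd.DataFrame,
    task: str = "LvsH",
    ranker: str = "ranksum",
    classifier: str = "random_forest",
    n_iterations: int = 3,
    n_top_features: int = 10,
    seed: int = 0,
) -> dict:
    """Compare compartment-separated (432) vs pooled (216) features on one
    task under identical CV seeds; reports both AUCs and their gap."""
    cases, _ = apply_extreme_conflict_exclusion(cases)
    _, labels = build_experiment(cases, task)
    out = {}
    for mode, table in (("separated", table_separated), ("pooled", table_pooled)):
        X, y, pids, names = modeling_matrix(table, labels)
        cv = CVConfig(
            n_iterations=n_iterations, n_top_features=n_top_features,
            ranker=ranker, seed=seed,
        )
        result = cross_validate(
            X, y, pids, names, ClassifierSpec(kind=classifier, seed=seed), cv
        )
        out[mode] = result.auc_mean
    out["delta_auc"] = out["separated"] - out["pooled"]
    return out


# ---------------------------------------------------------------------------
# External validation (train on all, apply frozen)
# ---------------------------------------------------------------------------

@dataclass
class FrozenModel:
    """A model trained once on the full primary cohort: standardization,
    ranking, classifier, and voting threshold are all frozen."""

    feature_names: list[str] = field(default_factory=list)
    top_features: list[str] = field(default_factory=list)
    mu: np.ndarray = None
    sd: np.ndarray = None
    model: object = None
    threshold: float = 0.5


def fit_frozen_model(
    table: pd.DataFrame,
    labels: dict[str, int],
    ranker: str = "ranksum",
    classifier: ClassifierSpec = ClassifierSpec(),
    n_top_features: int = 10,
) -> FrozenModel:
    X, y, pids, names = modeling_matrix(table, labels)
    from nucmorph.classify import _zscore_fit

    mu, sd = _zscore_fit(X)
    Xz = (X - mu) / sd
    ranking = rank_features(ranker, Xz, y, names, n_top=n_top_features)
    top = ranking.top(n_top_features)
    cols = [names.index(f) for f in top]
    model = classifier.build()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xz[:, cols], y)
    calls = score_patches(model, Xz[:, cols]) >= POSITIVE_SCORE_THRESHOLD
    fracs, labs = [], []
    for p in sorted(set(pids.tolist())):
        fracs.append(patch_fraction_positive(calls[pids == p]))
        labs.append(labels[p])
    threshold = optimal_threshold(np.array(fracs), np.array(labs))
    return FrozenModel(
        feature_names=names, top_features=top, mu=mu, sd=sd, model=model,
        threshold=threshold,
    )


def apply_frozen_model(
    frozen: FrozenModel, table: pd.DataFrame, labels: dict[str, int]
) -> dict:
    """Apply a frozen model to a held-out cohort; per-patient accuracy."""
    X, y, pids, names = modeling_matrix(table, labels)
    if names != frozen.feature_names:
        raise ValueError("validation feature catalog differs from training")
    Xz = (X - frozen.mu) / frozen.sd
    cols = [names.index(f) for f in frozen.top_features]
    calls = score_patches(frozen.model, Xz[:, cols]) >= POSITIVE_SCORE_THRESHOLD
    preds, truth = {}, {}
    for p in sorted(set(pids.tolist())):
        frac = patch_fraction_positive(calls[pids == p])
        preds[p] = int(frac >= frozen.threshold)
        truth[p] = labels[p]
    return {
        "accuracy": voting_accuracy(preds, truth),
        "predictions": preds,
        "threshold": frozen.threshold,
    }


def external_validation(
    train_cases: list[PatientCase],
    test_cases: list[PatientCase],
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    task: str = "LvsH",
    ranker: str = "ranksum",
    classifier: ClassifierSpec = ClassifierSpec(),
    n_top_features: int = 10,
) -> dict:
    """Train on the entire primary cohort, apply without retraining to the
    external cohort, and report per-patient voting accuracy."""
    train_ids = {c.patient_id for c in train_cases}
    test_ids = {c.patient_id for c in test_cases}
    if train_ids & test_ids:
        raise ValueError(f"overlapping patient ids: {sorted(train_ids & test_ids)}")
    train_cases, _ = apply_extreme_conflict_exclusion(train_cases)
    _, train_labels = build_experiment(train_cases, task)
    _, test_labels = build_experiment(test_cases, task)
    frozen = fit_frozen_model(
        train_table, train_labels, ranker=ranker, classifier=classifier,
        n_top_features=n_top_features,
    )
    return apply_frozen_model(frozen, test_table, test_labels)
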