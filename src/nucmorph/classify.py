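"""Patch classification under patient-grouped cross-validation.

The protocol: 100 iterations of randomly initialized 3-fold
cross-validation, with the fold split made at the patient level so that
no patient contributes patches to both the training and hold-out sides.
Within every training fold the features are z-scored, ranked, and the
top-n selected before the classifier is fit; the fitted standardization,
ranking, and classifier are then applied to the held-out patches. Each
iteration's AUC is computed on the pooled out-of-fold scores; the
per-patient voting threshold is learned on the training patients of the
same fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from nucmorph.ranking import rank_features
from nucmorph.voting import optimal_threshold, patch_fraction_positive

logger = logging.getLogger(__name__)

POSITIVE_SCORE_THRESHOLD = 0.5
MAX_FOLD_RETRIES = 10

CLASSIFIER_KINDS = ("random_forest", "neural_net", "svm", "lda")


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the four classifier families with its default hyperparameters.

    random_forest: bagging over 50 entropy-split trees, no depth cap.
    neural_net: 4 hidden layers of 10 logistic nodes, early stopping.
    svm: degree-3 polynomial kernel; margins squashed to (0, 1).
    lda: SVD solver (pseudo-inverse behavior on rank-deficient data).
    """

    kind: str = "random_forest"
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    def build(self, seed: int | None = None):
        rs = self.seed if seed is None else seed
        hp = dict(self.hyperparams)
        if self.kind == "random_forest":
            return RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 50),
                criterion=hp.pop("criterion", "entropy"),
                random_state=rs,
                **hp,
            )
        if self.kind == "neural_net":
            # L-BFGS: full-batch training is the reliable choice at the
            # patch counts this pipeline sees
            return MLPClassifier(
                hidden_layer_sizes=hp.pop("hidden_layer_sizes", (10, 10, 10, 10)),
                activation=hp.pop("activation", "logistic"),
                solver=hp.pop("solver", "lbfgs"),
                max_iter=hp.pop("max_iter", 500),
                random_state=rs,
                **hp,
            )
        if self.kind == "svm":
            return SVC(
                kernel=hp.pop("kernel", "poly"),
                degree=hp.pop("degree", 3),
                random_state=rs,
                **hp,
            )
        return LinearDiscriminantAnalysis(solver=hp.pop("solver", "svd"), **hp)


def score_patches(model, X: np.ndarray) -> np.ndarray:
    """Classifier score in [0, 1] (probability of the positive class, or a
    logistic squash of the SVM margin)."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    margin = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-margin))


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 3
    n_iterations: int = 100
    n_top_features: int = 10
    ranker: str = "ranksum"
    seed: int = 0

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class CVResult:
    per_iteration_auc: list[float]
    auc_mean: float
    auc_std: float
    per_iteration_voting_accuracy: list[float]
    voting_accuracy_mean: float
    out_of_fold_scores: np.ndarray  # (n_iterations, n_patches)
    selected_features: list[list[list[str]]]  # [iteration][fold] -> names


def grouped_folds(patient_ids, k: int, seed: int) -> list[list[str]]:
    """Partition patients into k folds of near-equal size (sizes differ by
    at most 1); all patches of a patient share its fold."""
    patients = sorted(set(patient_ids))
    if k > len(patients):
        raise ValueError(f"cannot make {k} folds from {len(patients)} patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(patients[idx])
    return [sorted(f) for f in folds]


def roc_auc(scores, labels) -> float:
    """Trapezoidal ROC AUC; identical to the normalized Mann-Whitney U
    statistic with half-credit for score ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = float(np.sum(ranks[labels == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def _zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and std; features constant to ~9 digits get unit
    scale so near-constant columns cannot blow up the standardized data."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-9 * (np.abs(mu) + 1.0)] = 1.0
    return mu, sd


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    patient_ids,
    feature_names: list[str],
    clf: ClassifierSpec = ClassifierSpec(),
    cv: CVConfig = CVConfig(),
) -> CVResult:
    """Patient-grouped k-fold cross-validation with in-fold ranking.

    `features` is a patches x features matrix with NaN-flagged patches
    already excluded; `labels` and `patient_ids` align with its rows.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    pids = np.asarray(patient_ids)
    if np.isnan(X).any():
        raise ValueError("NaN-flagged patches must be excluded before CV")
    patient_label = {p: int(y[pids == p][0]) for p in np.unique(pids)}
    if min(sum(1 for v in patient_label.values() if v == c) for c in (0, 1)) < 2:
        raise ValueError("need >= 2 patients per class")

    n = len(X)
    per_iter_auc: list[float] = []
    per_iter_vote: list[float] = []
    oof = np.full((cv.n_iterations, n), np.nan)
    selected: list[list[list[str]]] = []

    for it in range(cv.n_iterations):
        folds = None
        for retry in range(MAX_FOLD_RETRIES):
            fold_seed = int(
                np.random.SeedSequence([cv.seed, it, retry]).generate_state(1)[0]
                % (2**31)
            )
            candidate = grouped_folds(pids, cv.k_folds, fold_seed)
            ok = True
            for holdout in candidate:
                train_mask = ~np.isin(pids, holdout)
                if len(np.unique(y[train_mask])) < 2:
                    ok = False
            if ok:
                folds = candidate
                break
            logger.info("iteration %d: single-class training fold, resampling", it)
        if folds is None:
            raise RuntimeError("could not build folds with both classes in training")

        iter_selected: list[list[str]] = []
        patient_correct: dict[str, bool] = {}
        clf_seed = int(
            np.random.SeedSequence([clf.seed, cv.seed, it]).generate_state(1)[0]
            % (2**31)
        )
        for holdout in folds:
            test_mask = np.isin(pids, holdout)
            train_mask = ~test_mask
            # anti-leakage hard assertion: patient-disjoint train/test
            assert not set(pids[train_mask]) & set(pids[test_mask])
            mu, sd = _zscore_fit(X[train_mask])
            Xtr = (X[train_mask] - mu) / sd
            Xte = (X[test_mask] - mu) / sd
            ranking = rank_features(
                cv.ranker, Xtr, y[train_mask], feature_names, n_top=cv.n_top_features
            )
            top = ranking.top(cv.n_top_features)
            cols = [feature_names.index(f) for f in top]
            iter_selected.append(top)
            model = clf.build(seed=clf_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xtr[:, cols], y[train_mask])
            test_scores = score_patches(model, Xte[:, cols])
            oof[it, test_mask] = test_scores
            # patch voting: threshold learned on training patients only
            train_scores = score_patches(model, Xtr[:, cols])
            train_calls = train_scores >= POSITIVE_SCORE_THRESHOLD
            train_pids = pids[train_mask]
            frac = {
                p: patch_fraction_positive(train_calls[train_pids == p])
                for p in np.unique(train_pids)
            }
            thr = optimal_threshold(
                np.array([frac[p] for p in sorted(frac)]),
                np.array([patient_label[p] for p in sorted(frac)]),
            )
            test_calls = test_scores >= POSITIVE_SCORE_THRESHOLD
            test_pids = pids[test_mask]
            for p in np.unique(test_pids):
                f = patch_fraction_positive(test_calls[test_pids == p])
                patient_correct[p] = int(f >= thr) == patient_label[p]
        assert not np.isnan(oof[it]).any()  # every patch scored exactly once
        per_iter_auc.append(roc_auc(oof[it], y))
        per_iter_vote.append(float(np.mean(list(patient_correct.values()))))
        selected.append(iter_selected)

    return CVResult(
        per_iteration_auc=per_iter_auc,
        auc_mean=float(np.mean(per_iter_auc)),
        auc_std=float(np.std(per_iter_auc)),
        per_iteration_voting_accuracy=per_iter_vote,
        voting_accuracy_mean=float(np.mean(per_iter_vote)),
        out_of_fold_scores=oof,
        selected_features=selected,
    )
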