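"""Per-patient patch voting.

A patient's risk call is made by comparing the fraction of their patches
predicted positive against a patch-percentage threshold learned on
training patients. "Surpassed" is implemented inclusively (call positive
iff fraction >= threshold); candidate thresholds are the midpoints of
consecutive sorted unique training fractions plus {0, 1}; accuracy ties
resolve to the smallest candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PatientPrediction:
    patient_id: str
    fraction_positive: float
    threshold_used: float
    predicted_category: int

    def __post_init__(self):
        expected = int(self.fraction_positive >= self.threshold_used)
        if expected != self.predicted_category:
            raise ValueError("predicted_category inconsistent with threshold rule")


def patch_fraction_positive(patch_calls) -> float:
    """Fraction of a patient's scored patches predicted positive."""
    calls = np.asarray(patch_calls)
    if calls.size == 0:
        raise ValueError("patient has no scored patches")
    return float(np.mean(calls.astype(bool)))


def optimal_threshold(train_fractions, train_labels) -> float:
    """Threshold on the patch fraction maximizing training patient accuracy.

    Candidates are midpoints of consecutive sorted unique fractions plus
    {0, 1}; among equally accurate candidates the smallest is returned.
    """
    fr = np.asarray(train_fractions, dtype=float)
    yy = np.asarray(train_labels).astype(int)
    if len(np.unique(yy)) < 2:
        raise ValueError("both classes required among training patients")
    uniq = np.unique(fr)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    best_t, best_acc = 0.0, -1.0
    for t in np.sort(candidates):
        acc = float(np.mean((fr >= t).astype(int) == yy))
        if acc > best_acc:
            best_t, best_acc = float(t), acc
    return best_t


def voting_accuracy(predictions: dict[str, int], true_labels: dict[str, int]) -> float:
    """Fraction of patients whose risk category was called correctly."""
    if set(predictions) != set(true_labels):
        raise ValueError("prediction and truth patient ids do not match")
    if not predictions:
        raise ValueError("no patients to score")
    return float(
        np.mean([predictions[p] == true_labels[p] for p in predictions])
    )


def predict_patients(
    patch_scores, patch_patient_ids, threshold: float, score_cut: float = 0.5
) -> list[PatientPrediction]:
    """Apply a learned patch-percentage threshold to per-patch scores."""
    scores = np.asarray(patch_scores, dtype=float)
    pids = np.asarray(patch_patient_ids)
    out = []
    for p in sorted(set(pids.tolist())):
        frac = patch_fraction_positive(scores[pids == p] >= score_cut)
        out.append(
            PatientPrediction(
                patient_id=str(p),
                fraction_positive=frac,
                threshold_used=threshold,
                predicted_category=int(frac >= threshold),
            )
        )
    return out
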