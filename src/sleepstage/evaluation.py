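"""Splitting, cross-validation, staging metrics and model agreement.

Per-stage precision, recall and f1 are one-vs-rest marginals of the 5x5
confusion matrix; overall accuracy is the pooled trace/total.  f1 uses the
form TP / (TP + (FN + FP)/2), algebraically the harmonic mean of precision
and recall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import models as _models
from .flags import flag
from .signal_io import STAGES


def stratified_split(
    labels: np.ndarray, test_frac: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split preserving per-class proportions.

    The test set has ceil(n * test_frac) members, allocated per class
    proportionally (each class within one sample of its exact quota).
    """
    labels = np.asarray(labels)
    idx = np.arange(labels.size)
    if test_frac == 0:
        return idx, idx[:0]
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 members for a stratified split")
    train, test = train_test_split(
        idx, test_size=test_frac, stratify=labels, random_state=seed, shuffle=True
    )
    return np.sort(train), np.sort(test)


def kfold_cv(
    spec: "_models.ModelSpec",
    table: pd.DataFrame,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Stratified k-fold cross-validation accuracies (one per fold)."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    smallest = pd.Series(labels).value_counts().min()
    if k > smallest:
        raise ValueError(f"k={k} exceeds the smallest class size ({smallest})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(table, labels):
        model = _models.fit(spec, table.iloc[train_idx], labels[train_idx])
        pred = _models.predict(model, table.iloc[test_idx])
        accs.append(float(np.mean(pred == labels[test_idx])))
    return np.array(accs)


def confusion(
    y_true: np.ndarray, y_pred: np.ndarray, stages: tuple = STAGES
) -> pd.DataFrame:
    """5x5 confusion matrix, rows = true stage, columns = predicted stage."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred have different lengths")
    known = set(stages)
    bad = (set(y_true) | set(y_pred)) - known
    if bad:
        raise ValueError(f"labels outside the stage set: {sorted(bad)}")
    cm = pd.DataFrame(0, index=list(stages), columns=list(stages), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    return cm


@dataclass
class ClassificationReport:
    """Per-stage one-vs-rest metrics plus pooled accuracy."""

    per_stage: pd.DataFrame  # columns: test, correct, precision, recall, f1
    accuracy: float


def report(cm: pd.DataFrame) -> ClassificationReport:
    """Per-stage precision/recall/f1 and pooled accuracy from a confusion matrix.

    Zero-denominator metrics (a stage never predicted or absent from the
    test set) are reported as 0 and flagged.
    """
    total = int(cm.to_numpy().sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = {}
    for stage in cm.index:
        tp = int(cm.loc[stage, stage])
        fn = int(cm.loc[stage].sum()) - tp
        fp = int(cm[stage].sum()) - tp
        precision = tp / (tp + fp) if tp + fp else _zero(f"{stage}: no predicted positives")
        recall = tp / (tp + fn) if tp + fn else _zero(f"{stage}: no true positives")
        f1 = tp / (tp + (fn + fp) / 2) if tp + fn + fp else _zero(f"{stage}: empty class")
        rows[stage] = {
            "test": tp + fn,
            "correct": tp,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    per_stage = pd.DataFrame.from_dict(rows, orient="index")
    per_stage.index.name = "stage"
    accuracy = float(np.trace(cm.to_numpy()) / total)
    return ClassificationReport(per_stage=per_stage, accuracy=accuracy)


def _zero(reason: str) -> float:
    flag(f"zero denominator ({reason}); metric reported as 0")
    return 0.0


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def agreement_rate(pred_a: np.ndarray, pred_b: np.ndarray) -> float:
    """Fraction of epochs staged identically by two runs (coincidence rate)."""
    a = np.asarray(pred_a, dtype=object)
    b = np.asarray(pred_b, dtype=object)
    if a.size != b.size:
        raise ValueError("prediction vectors have different lengths")
    if a.size == 0:
        raise ValueError("empty prediction vectors")
    return float(np.mean(a == b))


def cohen_kappa(cm: pd.DataFrame) -> float:
    """Cohen's kappa (p_o − p_e)/(1 − p_e) from a confusion matrix."""
    m = cm.to_numpy(dtype=float)
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(m) / total
    p_e = float(np.sum(m.sum(axis=0) * m.sum(axis=1)) / total**2)
    if p_e == 1:
        raise ValueError("degenerate marginals: chance agreement is 1")
    return float((p_o - p_e) / (1 - p_e))
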