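"""Embedded feature screening: tree-ensemble weight coefficients thresholded
at 0.02.

A random forest is fitted to the labelled feature table and its mean
impurity-decrease importances (normalised to sum to 1) serve as per-feature
weight coefficients; features whose weight strictly exceeds the threshold
form the screened set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier


def fit_importances(
    table: pd.DataFrame,
    labels: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Fit a seeded random forest and return normalised feature weights.

    Returns a Series indexed by feature name, non-negative, summing to 1.
    """
    if table.isna().any().any():
        raise ValueError("feature table contains missing values")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to rank features")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(table.to_numpy(), labels)
    weights = forest.feature_importances_
    total = weights.sum()
    if total > 0:
        weights = weights / total
    return pd.Series(weights, index=table.columns, name="weight")


def select_by_threshold(importances: pd.Series | dict, threshold: float = 0.02) -> list[str]:
    """Feature names with weight strictly greater than ``threshold``,
    ordered by descending weight.

    Raises ``ValueError`` if nothing survives the threshold (with a hint to
    lower it).
    """
    imp = pd.Series(importances, dtype=float)
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    kept = imp[imp > threshold].sort_values(ascending=False)
    if kept.empty:
        raise ValueError(
            f"no feature weight exceeds {threshold}; lower the threshold "
            f"(max weight is {imp.max():.4f})"
        )
    return list(kept.index)
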