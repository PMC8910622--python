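"""The four classifier configurations used for staging.

Each classifier carries its own feature scaling: the SVM z-scores features,
the BPNN min-max scales them to [0, 1], and the tree models use the raw
features (splits are scale-free).  Default hyperparameters are the tuned
values of the benchmark study: SVM RBF with C=1.3, γ=0.03 (one-vs-rest);
BPNN with two hidden layers of 18 neurons, learning rate 0.1, early
stopping; decision tree with entropy criterion, depth 11, min leaf 11;
random forest with 100 trees, depth 22, min leaf 5 (Gini).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

#: Scaling that belongs to each classifier kind.
SCALING = {"svm": "zscore", "bpnn": "minmax", "dt": "none", "rf": "none"}

DEFAULT_PARAMS = {
    "svm": {"C": 1.3, "gamma": 0.03, "kernel": "rbf"},
    "bpnn": {
        "hidden_layer_sizes": (18, 18),
        "learning_rate_init": 0.1,
        "max_iter": 500,
    },
    "dt": {"criterion": "entropy", "max_depth": 11, "min_samples_leaf": 11},
    "rf": {
        "n_estimators": 100,
        "max_depth": 22,
        "min_samples_leaf": 5,
        "criterion": "gini",
    },
}


@dataclass
class ModelSpec:
    """A classifier kind plus hyperparameter overrides and seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCALING:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {sorted(SCALING)}")

    @property
    def scaling(self) -> str:
        return SCALING[self.kind]

    def resolved_params(self) -> dict:
        merged = dict(DEFAULT_PARAMS[self.kind])
        merged.update(self.params)
        return merged


def _make_estimator(spec: ModelSpec) -> Pipeline:
    p = spec.resolved_params()
    steps = []
    if spec.scaling == "zscore":
        steps.append(("scale", StandardScaler()))
    elif spec.scaling == "minmax":
        steps.append(("scale", MinMaxScaler()))
    if spec.kind == "svm":
        clf = OneVsRestClassifier(SVC(random_state=spec.seed, **p))
    elif spec.kind == "bpnn":
        clf = MLPClassifier(
            solver="sgd",
            momentum=0.9,
            early_stopping=True,
            validation_fraction=0.1,
            random_state=spec.seed,
            **p,
        )
    elif spec.kind == "dt":
        clf = DecisionTreeClassifier(random_state=spec.seed, **p)
    else:
        clf = RandomForestClassifier(random_state=spec.seed, **p)
    steps.append(("clf", clf))
    return Pipeline(steps)


@dataclass
class TrainedModel:
    """A fitted pipeline bound to the feature names it was trained with."""

    spec: ModelSpec
    pipeline: Pipeline
    feature_names: list[str]
    version: str = "sleepstage-model-1"


def fit(spec: ModelSpec, table: pd.DataFrame, labels: np.ndarray) -> TrainedModel:
    """Fit a classifier (scaler included) on a labelled feature table.

    The scaler parameters are estimated from this table only, so held-out
    evaluation stays leakage-free.
    """
    if table.isna().any().any():
        raise ValueError("feature table contains NaN")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 stages in the training labels")
    pipe = _make_estimator(spec)
    pipe.fit(table.to_numpy(), labels)
    return TrainedModel(spec=spec, pipeline=pipe, feature_names=list(table.columns))


def predict(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """Predict one stage per row; columns are matched by name, not position."""
    missing = set(model.feature_names) - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if len(table) == 0:
        return np.array([], dtype=object)
    x = table[model.feature_names].to_numpy()
    return model.pipeline.predict(x).astype(object)


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise ValueError(f"{path} is not a sleepstage model file")
    return model
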