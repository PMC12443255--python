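"""Soft-voting ensemble of tree-based learners.

The final classifier combines Random Forest, Gradient Boosting and
histogram Gradient Boosting by weighted averaging of their predicted class
probabilities (soft voting), which damps the fluctuations of any single
member while keeping each member's capacity. Members are pluggable by name
so single-model comparisons reuse the same machinery. Hyperparameters
default to the scikit-learn defaults with only the seed pinned; everything
is surfaced through :class:`EnsembleConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .sampling import LabeledMatrix

__all__ = [
    "EnsembleConfig",
    "TrainedEnsemble",
    "MEMBER_FACTORIES",
    "train_ensemble",
    "soft_vote",
    "predict",
    "save_ensemble",
    "load_ensemble",
]

_FORMAT_VERSION = 1

MEMBER_FACTORIES = {
    "random_forest": lambda seed, p: RandomForestClassifier(random_state=seed, **p),
    "gradient_boosting": lambda seed, p: GradientBoostingClassifier(random_state=seed, **p),
    "hist_gradient_boosting": lambda seed, p: HistGradientBoostingClassifier(
        random_state=seed, **p
    ),
    # extra members for single-model comparison harnesses
    "logistic_regression": lambda seed, p: LogisticRegression(
        random_state=seed, max_iter=1000, **p
    ),
    "svm": lambda seed, p: SVC(random_state=seed, probability=True, **p),
    "knn": lambda seed, p: KNeighborsClassifier(**p),
    "decision_tree": lambda seed, p: DecisionTreeClassifier(random_state=seed, **p),
}

DEFAULT_MEMBERS = ("random_forest", "gradient_boosting", "hist_gradient_boosting")


@dataclass
class EnsembleConfig:
    """Declarative ensemble specification.

    ``member_params`` maps member name -> keyword overrides for that
    learner; weights default to equal and are normalized at voting time.
    """

    members: tuple[str, ...] = DEFAULT_MEMBERS
    weights: Optional[tuple[float, ...]] = None
    seed: int = 0
    member_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        if not self.members:
            raise ValueError("need at least one ensemble member")
        unknown = [m for m in self.members if m not in MEMBER_FACTORIES]
        if unknown:
            raise ValueError(f"unknown member(s) {unknown}; choose from {sorted(MEMBER_FACTORIES)}")
        if self.weights is not None:
            self.weights = tuple(float(w) for w in self.weights)
            if len(self.weights) != len(self.members):
                raise ValueError("weights length must equal member count")
            if any(w < 0 for w in self.weights) or sum(self.weights) <= 0:
                raise ValueError("weights must be non-negative with positive sum")

    def resolved_weights(self) -> np.ndarray:
        w = np.asarray(
            self.weights if self.weights is not None else [1.0] * len(self.members)
        )
        return w / w.sum()


@dataclass
class TrainedEnsemble:
    """Fitted members plus the config echo, feature width and class order."""

    members: list
    config: EnsembleConfig
    n_features: int
    classes: np.ndarray

    @property
    def positive_class(self):
        return self.classes[-1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got shape {X.shape}"
            )
        probs = [m.predict_proba(X) for m in self.members]
        return soft_vote(probs, self.config.resolved_weights())

    def predict_positive_proba(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, -1]


def train_ensemble(data: LabeledMatrix, config: EnsembleConfig | None = None) -> TrainedEnsemble:
    """Fit every member on the same data with the shared seed."""
    config = config or EnsembleConfig()
    classes = np.unique(data.y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    members = []
    for name in config.members:
        params = dict(config.member_params.get(name, {}))
        model = MEMBER_FACTORIES[name](config.seed, params)
        model.fit(data.X, data.y)
        members.append(model)
    return TrainedEnsemble(
        members=members,
        config=config,
        n_features=data.X.shape[1],
        classes=classes,
    )


def soft_vote(prob_rows: Sequence[np.ndarray], weights: Sequence[float] | None = None) -> np.ndarray:
    """Weighted arithmetic mean of member probability arrays.

    Weights are normalized to sum 1; arrays must agree in shape.
    """
    arrays = [np.asarray(p, dtype=float) for p in prob_rows]
    if not arrays:
        raise ValueError("need at least one probability array")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("probability arrays must have identical shapes")
    w = np.asarray(weights if weights is not None else [1.0] * len(arrays), dtype=float)
    if w.shape[0] != len(arrays):
        raise ValueError("weights length must equal number of members")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    return np.tensordot(w, np.stack(arrays), axes=1)


def predict(
    model: TrainedEnsemble, X: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and positive-class probabilities.

    A sample is positive iff its combined probability is >= threshold
    (a tie at the threshold resolves to positive).
    """
    prob_pos = model.predict_positive_proba(X)
    neg, pos = model.classes[0], model.classes[-1]
    labels = np.where(prob_pos >= threshold, pos, neg)
    return labels, prob_pos


def save_ensemble(model: TrainedEnsemble, path: str | Path) -> None:
    """Persist to a single archive with a format version and config echo."""
    joblib.dump(
        {
            "format_version": _FORMAT_VERSION,
            "config": model.config,
            "n_features": model.n_features,
            "classes": model.classes,
            "members": model.members,
        },
        path,
    )


def load_ensemble(path: str | Path) -> TrainedEnsemble:
    payload = joblib.load(path)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version: {payload.get('format_version')}")
    return TrainedEnsemble(
        members=payload["members"],
        config=payload["config"],
        n_features=payload["n_features"],
        classes=payload["classes"],
    )
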