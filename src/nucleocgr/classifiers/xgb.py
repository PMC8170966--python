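"""Gradient-boosted trees (XGBoost) with the logistic objective."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from xgboost import XGBClassifier


@dataclass
class XGBModel:
    estimator: XGBClassifier
    backend: str = "xgboost"

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(X)[:, 1]


def train_xgboost(
    features: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 100,
    depth: int = 6,
    eta: float = 0.3,
    seed: int = 0,
) -> XGBModel:
    """Boosted trees, each fitting the residual of the previous ensemble."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    clf = XGBClassifier(
        n_estimators=n_trees,
        max_depth=depth,
        learning_rate=eta,
        objective="binary:logistic",
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    clf.fit(X, y)
    return XGBModel(estimator=clf)
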