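"""RBF-kernel SVM with an exhaustive (C, gamma) grid search.

The grid is scanned in order (C outer, gamma inner) with seeded stratified
cross-validation on the training data only; the first pair achieving the
best mean accuracy wins (deterministic tie-break), and the model is refit on
the full training set.  Decision values are mapped through a logistic so all
backends emit probability-like scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: classic exponential libsvm-style grids
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass
class SVMModel:
    estimator: SVC
    C: float
    gamma: float
    cv_accuracy: float
    backend: str = "svm"

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        margin = self.estimator.decision_function(X)
        return 1.0 / (1.0 + np.exp(-margin))


def train_svm_grid(
    features: np.ndarray,
    labels: np.ndarray,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    cv_folds: int = 3,
    seed: int = 0,
) -> SVMModel:
    """Grid-optimize (C, gamma) by internal CV accuracy, then refit."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    if not C_grid or not gamma_grid:
        raise ValueError("empty parameter grid")
    if len(C_grid) == 1 and len(gamma_grid) == 1:
        best_C, best_gamma, best_acc = C_grid[0], gamma_grid[0], float("nan")
    else:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
        best_C = best_gamma = None
        best_acc = -1.0
        for C in C_grid:
            for gamma in gamma_grid:
                correct = 0
                for tr, te in splits:
                    clf = SVC(kernel="rbf", C=C, gamma=gamma)
                    clf.fit(X[tr], y[tr])
                    correct += int((clf.predict(X[te]) == y[te]).sum())
                acc = correct / len(y)
                if acc > best_acc:  # strict: first in scan order wins ties
                    best_acc, best_C, best_gamma = acc, C, gamma
    final = SVC(kernel="rbf", C=best_C, gamma=best_gamma)
    final.fit(X, y)
    return SVMModel(estimator=final, C=best_C, gamma=best_gamma, cv_accuracy=best_acc)
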