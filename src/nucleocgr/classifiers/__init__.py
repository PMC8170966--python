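"""Classifier backends and score-level utilities.

Every trainer returns an object exposing ``predict_scores(X) -> array`` of
positive-class probabilities in [0, 1] (higher = more likely
nucleosome-forming) so that AUC computation and multi-model averaging are
uniform across backends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nucleocgr.classifiers.elm import ELMModel, train_elm
from nucleocgr.classifiers.svm import SVMModel, train_svm_grid, DEFAULT_C_GRID, DEFAULT_GAMMA_GRID
from nucleocgr.classifiers.xgb import XGBModel, train_xgboost
from nucleocgr.classifiers.neural import NeuralModel, train_mlp, train_cnn


@dataclass
class ScoreSet:
    """Per-sample positive-class scores with 0.5-thresholded labels."""

    scores: np.ndarray

    @property
    def labels_pred(self) -> np.ndarray:
        return (self.scores >= 0.5).astype(int)

    def __len__(self) -> int:
        return len(self.scores)


def ensemble_average(score_sets: list[ScoreSet]) -> ScoreSet:
    """Simple averaging of per-model positive-class probabilities."""
    if not score_sets:
        raise ValueError("no score sets to average")
    n = len(score_sets[0])
    if any(len(s) != n for s in score_sets):
        raise ValueError("score sets have mismatched lengths")
    return ScoreSet(np.mean([s.scores for s in score_sets], axis=0))


__all__ = [
    "ELMModel",
    "train_elm",
    "SVMModel",
    "train_svm_grid",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "XGBModel",
    "train_xgboost",
    "NeuralModel",
    "train_mlp",
    "train_cnn",
    "ScoreSet",
    "ensemble_average",
]
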