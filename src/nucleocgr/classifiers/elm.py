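"""Extreme learning machine: random hidden layer, least-squares output weights.

A single-hidden-layer network whose input weights and biases are drawn
randomly (seeded, so reproducible) and never trained; only the output
weights are fitted, by ridge-regularized least squares of the hidden
activations against one-hot labels.  With at least as many hidden units as
distinct training points the least-squares fit interpolates the training
set, which is the backend's contract test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ELMModel:
    input_weights: np.ndarray  # (n_features, n_hidden)
    biases: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_hidden, 2)
    seed: int
    backend: str = "elm"

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(X @ self.input_weights + self.biases)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability via a logistic of the output margin."""
        O = self._hidden(X) @ self.output_weights
        return _sigmoid(O[:, 1] - O[:, 0])


def train_elm(
    features: np.ndarray,
    labels: np.ndarray,
    n_hidden: int = 500,
    seed: int = 0,
    ridge: float = 1e-6,
) -> ELMModel:
    """Fit an ELM with sigmoid activations and ridge-stabilized output solve."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("training labels must contain both classes 0 and 1")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((X.shape[1], n_hidden))
    b = rng.standard_normal(n_hidden)
    H = _sigmoid(X @ W + b)
    T = np.eye(2)[y]  # one-hot targets
    # ridge least squares: beta = (H'H + ridge I)^-1 H'T
    A = H.T @ H + ridge * np.eye(n_hidden)
    beta = np.linalg.solve(A, H.T @ T)
    return ELMModel(input_weights=W, biases=b, output_weights=beta, seed=seed)
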