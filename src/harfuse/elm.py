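"""Extreme learning machine base classifiers.

An ELM is a single-hidden-layer network whose input weights and biases
are drawn at random (here uniform on [-1, 1]) and never trained; only
the output weights are fitted, by ridge-regularized least squares of
the hidden activations against one-hot class targets.  Training is a
single linear solve, which is what makes a pool of per-sensor experts
cheap to build, and the random hidden layer is itself a source of
ensemble diversity.

One model is trained per channel group (sensor unit); downstream the
model's raw scores become an expert's decision vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DataError

__all__ = ["ELMModel", "train_elm", "predict_scores", "predict_labels"]


@dataclass
class ELMModel:
    input_weights: np.ndarray   # (hidden, features)
    biases: np.ndarray          # (hidden,)
    output_weights: np.ndarray  # (hidden, classes)
    class_order: list = field(default_factory=list)
    activation: str = "sigmoid"
    group_id: str | None = None
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]


def _hidden(model_W: np.ndarray, b: np.ndarray, X: np.ndarray) -> np.ndarray:
    z = X @ model_W.T + b
    return 1.0 / (1.0 + np.exp(-z))


def train_elm(
    X: np.ndarray,
    y: np.ndarray,
    hidden: int = 100,
    ridge: float = 1e-6,
    seed: int = 0,
    group_id: str | None = None,
) -> ELMModel:
    """Fit an ELM on normalized feature rows ``X`` with labels ``y``.

    ``ridge > 0`` solves ``(H'H + ridge I) beta = H'T``; ``ridge = 0``
    uses the pseudoinverse (exact interpolation when ``hidden`` is at
    least the number of rows and H has full row rank).  Deterministic
    for identical inputs and seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ContractError("X must be 2-D with one label per row")
    if hidden < 1:
        raise DataError("hidden must be >= 1")
    if ridge < 0:
        raise DataError("ridge must be >= 0")
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise DataError("training labels contain a single class")
    if X.shape[0] < len(classes):
        raise DataError("need at least as many rows as classes")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(hidden, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=hidden)
    H = _hidden(W, b, X)
    idx = {c: i for i, c in enumerate(classes)}
    T = np.zeros((X.shape[0], len(classes)))
    T[np.arange(len(y)), [idx[v] for v in y]] = 1.0
    if ridge > 0:
        beta = np.linalg.solve(H.T @ H + ridge * np.eye(hidden), H.T @ T)
    else:
        beta = np.linalg.pinv(H) @ T
    return ELMModel(
        input_weights=W,
        biases=b,
        output_weights=beta,
        class_order=classes,
        group_id=group_id,
        seed=seed,
    )


def predict_scores(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Raw (unnormalized) class scores H @ beta, shape (rows, classes)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ContractError(
            f"expected {model.n_features} features, got shape {X.shape}"
        )
    H = _hidden(model.input_weights, model.biases, X)
    return H @ model.output_weights


def predict_labels(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Argmax of the score rows; ties go to the lowest class index."""
    scores = predict_scores(model, X)
    idx = np.argmax(scores, axis=1)  # first maximum = lowest class index
    return np.asarray([model.class_order[i] for i in idx])
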