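"""One-vs-rest family classifiers over distance-pair feature vectors.

Each protein family gets its own soft-margin SVM trained on positive
(within-superfamily) and negative (outside-superfamily) feature vectors.
Count vectors are scaled to unit Euclidean norm before training so that
sequence length does not dominate the kernel.  The default kernel is
linear; the discriminative score of a test protein is the standard kernel
expansion

    f(v) = sum_i alpha_i K(x_i, v) + b

with label-signed dual coefficients alpha_i, so higher scores mean
more likely family membership.  The expansion is computed explicitly from
the stored dual coefficients and training vectors, which is what makes the
discriminant-weight analysis (w = M alpha) checkable against the scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .distance_features import DistanceFeatureVector, vector_length


def normalize_vector(v: DistanceFeatureVector | np.ndarray) -> np.ndarray:
    """Scale to unit L2 norm; the all-zero vector is returned unchanged."""
    arr = np.asarray(v.values if isinstance(v, DistanceFeatureVector) else v, dtype=float)
    norm = np.linalg.norm(arr)
    if norm == 0.0:
        return arr.copy()
    return arr / norm


def normalize_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return X / norms


@dataclass
class SVMConfig:
    """Classifier configuration.

    kernel: "linear" (default) or "rbf".
    C: soft-margin regularization constant.
    normalize: unit-L2-normalize input count vectors before training/scoring.
    balance_classes: weight the minority class by the inverse class ratio so
        the heavily unbalanced family splits do not collapse to the majority.
    tol: dual solver stopping tolerance (fixed, keeps training deterministic).
    gamma: RBF width ("scale" or a float); ignored for the linear kernel.
    """

    kernel: str = "linear"
    C: float = 1.0
    normalize: bool = True
    balance_classes: bool = True
    tol: float = 1e-6
    gamma: float | str = "scale"

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class TrainingSet:
    """Labeled feature matrix for one family (rows are proteins)."""

    X: np.ndarray
    labels: np.ndarray
    ids: list[str]
    d_max: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2 or not (len(self.X) == len(self.labels) == len(self.ids)):
            raise ValueError("X, labels, ids must agree in length")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 / -1")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in training set")
        if self.X.shape[1] != vector_length(self.d_max):
            raise ValueError(
                f"feature dimension {self.X.shape[1]} does not match d_max={self.d_max}"
            )

    @classmethod
    def from_vectors(
        cls, vectors: Sequence[DistanceFeatureVector], labels: Sequence[int]
    ) -> "TrainingSet":
        if not vectors:
            raise ValueError("empty training set")
        d_max = vectors[0].d_max
        X = np.stack([np.asarray(v.values, dtype=float) for v in vectors])
        return cls(
            X=X,
            labels=np.asarray(labels, dtype=int),
            ids=[v.sequence_id for v in vectors],
            d_max=d_max,
        )


@dataclass
class TrainedModel:
    """A trained family classifier.

    ``alpha`` holds label-signed dual coefficients (alpha_i * y_i) for every
    training sample, zero for non-support vectors; ``X_train`` holds the
    training vectors exactly as the kernel saw them (normalized if the
    config says so), in the same order as alpha.
    """

    alpha: np.ndarray
    bias: float
    X_train: np.ndarray
    ids: list[str]
    labels: np.ndarray
    config: SVMConfig
    d_max: int
    model_id: str = "family-svm"
    _gamma_value: float = field(default=0.0, repr=False)

    def kernel_matrix(self, V: np.ndarray) -> np.ndarray:
        """K(x_i, v_j) for training vectors x_i against query rows v_j."""
        if self.config.kernel == "linear":
            return self.X_train @ V.T
        sq = (
            np.sum(self.X_train**2, axis=1)[:, None]
            + np.sum(V**2, axis=1)[None, :]
            - 2.0 * self.X_train @ V.T
        )
        return np.exp(-self._gamma_value * np.maximum(sq, 0.0))


def train_family_classifier(
    ts: TrainingSet, config: SVMConfig | None = None
) -> TrainedModel:
    """Fit a soft-margin SVM on one family's training vectors.

    Deterministic for a fixed config and input order (fixed tolerance, no
    randomized initialization).  Raises on single-class input.
    """
    config = config or SVMConfig()
    classes = set(np.unique(ts.labels))
    if classes != {-1, 1}:
        raise ValueError(
            "training set must contain both positive and negative samples; "
            f"got labels {sorted(classes)}"
        )
    X = normalize_matrix(ts.X) if config.normalize else np.asarray(ts.X, dtype=float)

    class_weight = None
    if config.balance_classes:
        n_pos = int((ts.labels == 1).sum())
        n_neg = int((ts.labels == -1).sum())
        if n_pos <= n_neg:
            class_weight = {1: n_neg / n_pos, -1: 1.0}
        else:
            class_weight = {1: 1.0, -1: n_pos / n_neg}

    svc = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma,
        tol=config.tol,
        class_weight=class_weight,
        shrinking=True,
        cache_size=200,
    )
    svc.fit(X, ts.labels)

    alpha = np.zeros(len(X), dtype=float)
    alpha[svc.support_] = svc.dual_coef_[0]
    gamma_value = float(svc._gamma) if config.kernel == "rbf" else 0.0

    return TrainedModel(
        alpha=alpha,
        bias=float(svc.intercept_[0]),
        X_train=X,
        ids=list(ts.ids),
        labels=ts.labels.copy(),
        config=config,
        d_max=ts.d_max,
        _gamma_value=gamma_value,
    )


def score(model: TrainedModel, v: DistanceFeatureVector | np.ndarray) -> float:
    """Discriminative score of one test vector (higher = more family-like)."""
    return float(score_many(model, [v])[0])


def score_many(
    model: TrainedModel,
    vectors: Sequence[DistanceFeatureVector | np.ndarray],
) -> np.ndarray:
    """Kernel-expansion scores for a batch of test vectors."""
    rows = []
    for v in vectors:
        arr = np.asarray(
            v.values if isinstance(v, DistanceFeatureVector) else v, dtype=float
        )
        if arr.shape != (model.X_train.shape[1],):
            raise ValueError(
                f"feature dimension {arr.shape} does not match model "
                f"dimension {model.X_train.shape[1]} (d_max={model.d_max})"
            )
        rows.append(normalize_vector(arr) if model.config.normalize else arr)
    V = np.stack(rows)
    K = model.kernel_matrix(V)
    return model.alpha @ K + model.bias


MODEL_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a model to a self-describing JSON file (sparse training matrix)."""
    X = model.X_train
    sparse_rows = []
    for row in X:
        nz = np.nonzero(row)[0]
        sparse_rows.append([[int(j), float(row[j])] for j in nz])
    payload = {
        "format": "distsvm-model",
        "version": MODEL_FORMAT_VERSION,
        "model_id": model.model_id,
        "d_max": model.d_max,
        "n_features": int(X.shape[1]),
        "bias": model.bias,
        "alpha": [float(a) for a in model.alpha],
        "labels": [int(y) for y in model.labels],
        "ids": model.ids,
        "config": asdict(model.config),
        "gamma_value": model._gamma_value,
        "X_train_sparse": sparse_rows,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "distsvm-model":
        raise ValueError(f"{path}: not a distsvm model file")
    n_features = payload["n_features"]
    X = np.zeros((len(payload["X_train_sparse"]), n_features), dtype=float)
    for i, row in enumerate(payload["X_train_sparse"]):
        for j, val in row:
            X[i, j] = val
    return TrainedModel(
        alpha=np.asarray(payload["alpha"], dtype=float),
        bias=float(payload["bias"]),
        X_train=X,
        ids=list(payload["ids"]),
        labels=np.asarray(payload["labels"], dtype=int),
        config=SVMConfig(**payload["config"]),
        d_max=int(payload["d_max"]),
        model_id=payload.get("model_id", "family-svm"),
        _gamma_value=float(payload.get("gamma_value", 0.0)),
    )
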