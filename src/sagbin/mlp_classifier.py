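"""Multi-layer perceptron over trimer-frequency vectors.

Architecture and defaults follow the classic feed-forward classifier this
stage reconstructs: a single hidden layer of ``(n_features + n_classes) // 2``
logistic units, a softmax output trained by full-batch gradient descent with
learning rate 0.3 and momentum 0.2 for 500 epochs, cross-entropy loss, and
per-feature z-score standardization using training-set statistics stored in
the model. All of these are exposed as hyperparameters.

The softmax output is the per-class "confidence score": a read is assigned to
its top class only when that confidence strictly exceeds the threshold
(default 0.9). The threshold can be calibrated on a labeled holdout that
contains decoy reads — reads whose true population is not among the model's
classes — by maximizing Youden's J = TPR - FPR over a threshold grid, the
operational form of minimizing false positives while maximizing true
positives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import SeqRecord
from .trimer_features import TrainingSegment, feature_matrix

__all__ = [
    "Hyperparameters",
    "MLPModel",
    "Prediction",
    "CalibrationResult",
    "train_mlp",
    "segments_to_xy",
    "predict",
    "predict_batch",
    "assign_reads",
    "calibrate_threshold",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Hyperparameters:
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 500
    hidden_units: int = 0      # 0 -> (n_features + n_classes) // 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate must be > 0 and epochs >= 1")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")


@dataclass(frozen=True)
class Prediction:
    read_id: str
    posteriors: np.ndarray
    top_label: str
    confidence: float


@dataclass
class MLPModel:
    """Trained network plus the feature convention it was trained under.

    The model refuses to score vectors produced under a different convention
    (k-mer size or strand symmetry): train and test must share a space.
    """

    class_labels: list[str]
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    hyper: Hyperparameters
    training_log: list[float] = field(default_factory=list)
    feature_convention: dict = field(
        default_factory=lambda: {"k": 3, "strand_symmetric": True}
    )

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def check_convention(self, convention: dict) -> None:
        if convention != self.feature_convention:
            raise ValueError(
                f"feature convention mismatch: model was trained under "
                f"{self.feature_convention}, got {convention}"
            )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "class_labels": self.class_labels,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "hyper": vars(self.hyper) | {},
            "training_log": self.training_log,
            "feature_convention": self.feature_convention,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "MLPModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {doc.get('format_version')}"
            )
        return cls(
            class_labels=list(doc["class_labels"]),
            W1=np.array(doc["W1"]),
            b1=np.array(doc["b1"]),
            W2=np.array(doc["W2"]),
            b2=np.array(doc["b2"]),
            mu=np.array(doc["mu"]),
            sigma=np.array(doc["sigma"]),
            hyper=Hyperparameters(**doc["hyper"]),
            training_log=list(doc["training_log"]),
            feature_convention=dict(doc["feature_convention"]),
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def loss_and_grads(
    params: dict[str, np.ndarray], X: np.ndarray, Y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy and its exact gradients (backpropagation).

    ``X`` is the standardized feature matrix, ``Y`` one-hot targets. Exposed
    as a pure function so the gradients can be checked against finite
    differences.
    """
    W1, b1, W2, b2 = params["W1"], params["b1"], params["W2"], params["b2"]
    n = X.shape[0]
    A = _sigmoid(X @ W1 + b1)
    P = _softmax(A @ W2 + b2)
    eps = 1e-12
    loss = float(-np.sum(Y * np.log(P + eps)) / n)
    dlogits = (P - Y) / n
    gW2 = A.T @ dlogits
    gb2 = dlogits.sum(axis=0)
    dA = dlogits @ W2.T
    dZ = dA * A * (1.0 - A)
    gW1 = X.T @ dZ
    gb1 = dZ.sum(axis=0)
    return loss, {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


def segments_to_xy(
    segments: Sequence[TrainingSegment],
) -> tuple[np.ndarray, list[str]]:
    """Stack training-segment frequency vectors into (X, labels)."""
    X = np.stack([s.vector.freqs for s in segments])
    return X, [s.label for s in segments]


def train_mlp(
    X: np.ndarray,
    labels: Sequence[str],
    hyper: Hyperparameters = Hyperparameters(),
    feature_convention: dict | None = None,
) -> MLPModel:
    """Train on labeled frequency vectors; deterministic for a fixed seed.

    Requires at least 2 classes and 10 examples per class. Raises on NaN loss
    with diagnostics rather than returning a broken model.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    class_labels = sorted(set(labels))
    if len(class_labels) < 2:
        raise ValueError(
            f"training requires >= 2 classes, got {class_labels}: "
            "a single-class model cannot discriminate"
        )
    counts = {c: labels.count(c) for c in class_labels}
    thin = [c for c, n in counts.items() if n < 10]
    if thin:
        raise ValueError(f"classes with fewer than 10 examples: {thin}")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN rows (no-signal inputs?)")

    n, d = X.shape
    C = len(class_labels)
    H = hyper.hidden_units or (d + C) // 2
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma == 0] = 1.0
    Xs = (X - mu) / sigma
    lab_idx = {c: i for i, c in enumerate(class_labels)}
    Y = np.zeros((n, C))
    Y[np.arange(n), [lab_idx[l] for l in labels]] = 1.0

    rng = np.random.default_rng(hyper.seed)
    params = {
        "W1": rng.uniform(-0.5, 0.5, size=(d, H)),
        "b1": rng.uniform(-0.5, 0.5, size=H),
        "W2": rng.uniform(-0.5, 0.5, size=(H, C)),
        "b2": rng.uniform(-0.5, 0.5, size=C),
    }
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    log: list[float] = []
    for epoch in range(hyper.epochs):
        loss, grads = loss_and_grads(params, Xs, Y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={loss}; "
                f"lr={hyper.learning_rate}, momentum={hyper.momentum}"
            )
        log.append(loss)
        for k in params:
            velocity[k] = hyper.momentum * velocity[k] - hyper.learning_rate * grads[k]
            params[k] = params[k] + velocity[k]

    return MLPModel(
        class_labels=class_labels,
        W1=params["W1"],
        b1=params["b1"],
        W2=params["W2"],
        b2=params["b2"],
        mu=mu,
        sigma=sigma,
        hyper=hyper,
        training_log=log,
        feature_convention=feature_convention
        or {"k": 3, "strand_symmetric": True},
    )


def _posteriors(model: MLPModel, X: np.ndarray) -> np.ndarray:
    Xs = (np.asarray(X, dtype=float) - model.mu) / model.sigma
    A = _sigmoid(Xs @ model.W1 + model.b1)
    return _softmax(A @ model.W2 + model.b2)


def predict_batch(
    model: MLPModel, X: np.ndarray, ids: Sequence[str]
) -> list[Prediction]:
    P = _posteriors(model, X)
    top = P.argmax(axis=1)  # ties resolve to the lowest class index
    return [
        Prediction(
            read_id=ids[i],
            posteriors=P[i],
            top_label=model.class_labels[top[i]],
            confidence=float(P[i, top[i]]),
        )
        for i in range(len(ids))
    ]


def predict(model: MLPModel, vector: np.ndarray, read_id: str = "") -> Prediction:
    """Score one frequency vector; posteriors sum to 1 (softmax)."""
    return predict_batch(model, np.asarray(vector)[None, :], [read_id])[0]


def assign_reads(
    model: MLPModel,
    reads: Sequence[SeqRecord],
    threshold: float = 0.9,
) -> tuple[dict[str, Prediction], list[str]]:
    """Partition reads into (assigned, unassigned) at a confidence threshold.

    A read is assigned iff its confidence is STRICTLY greater than the
    threshold. No-signal reads (too short / all-ambiguous) are reported as
    unassigned — they cannot be scored at all.
    """
    if not 1.0 / model.n_classes <= threshold <= 1.0:
        raise ValueError(
            f"threshold must be in [1/C, 1] = [{1.0 / model.n_classes:.3f}, 1]"
        )
    sym = bool(model.feature_convention.get("strand_symmetric", True))
    X, no_signal = feature_matrix(reads, strand_symmetric=sym)
    no_signal_set = set(no_signal)
    scorable = [i for i in range(len(reads)) if i not in no_signal_set]
    assigned: dict[str, Prediction] = {}
    unassigned: list[str] = [reads[i].id for i in no_signal]
    if scorable:
        preds = predict_batch(
            model, X[scorable], [reads[i].id for i in scorable]
        )
        for p in preds:
            if p.confidence > threshold:
                assigned[p.read_id] = p
            else:
                unassigned.append(p.read_id)
    return assigned, unassigned


@dataclass(frozen=True)
class CalibrationResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    youden_j: np.ndarray
    chosen_threshold: float

    def to_table(self) -> list[dict]:
        return [
            {
                "threshold": round(float(t), 10),
                "tpr": float(tp),
                "fpr": float(fp),
                "youden_j": float(j),
            }
            for t, tp, fp, j in zip(self.thresholds, self.tpr, self.fpr, self.youden_j)
        ]


def calibrate_threshold(
    model: MLPModel,
    X_holdout: np.ndarray,
    true_labels: Sequence[str],
    grid: np.ndarray | None = None,
) -> CalibrationResult:
    """Pick the confidence threshold on a decoy-containing labeled holdout.

    TPR(t): fraction of non-decoy holdout examples assigned (confidence > t)
    to their true class. FPR(t): fraction of decoy examples (true label
    outside the model's classes) assigned to any class. The chosen threshold
    maximizes Youden's J = TPR - FPR, ties broken toward the higher
    threshold. Without decoys the false-positive rate is unmeasurable and
    calibration refuses to run.
    """
    if grid is None:
        grid = np.round(np.arange(0.50, 0.995, 0.01), 10)
    true_labels = list(true_labels)
    class_set = set(model.class_labels)
    decoy_mask = np.array([lab not in class_set for lab in true_labels])
    if not decoy_mask.any():
        raise ValueError(
            "holdout contains no decoy examples: false-positive rate is "
            "unmeasurable, refusing to calibrate"
        )
    P = _posteriors(model, X_holdout)
    top = P.argmax(axis=1)
    conf = P[np.arange(len(P)), top]
    correct = np.array(
        [
            (not decoy_mask[i]) and model.class_labels[top[i]] == true_labels[i]
            for i in range(len(true_labels))
        ]
    )
    n_pos = int((~decoy_mask).sum())
    n_decoy = int(decoy_mask.sum())
    tpr = np.array(
        [np.sum(correct & (conf > t)) / n_pos for t in grid]
    )
    fpr = np.array(
        [np.sum(decoy_mask & (conf > t)) / n_decoy for t in grid]
    )
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())[-1]  # ties -> higher threshold
    return CalibrationResult(
        thresholds=grid,
        tpr=tpr,
        fpr=fpr,
        youden_j=j,
        chosen_threshold=float(grid[best]),
    )
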