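"""Trainable low/high-risk classifier over thermogram feature vectors.

A compact, reproducible stand-in for a learned risk model: logistic
regression (default) or a small MLP, both behind a standardising pipeline
with balanced class weighting for the ~8:1 low:high cohort imbalance.
Training uses a fixed stratified 80/20 split and records held-out F1,
precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, precision_score, recall_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_NAMES, FeatureVector

LABELS = ("low", "high")


@dataclass
class TrainingMeta:
    seed: int
    n_low: int
    n_high: int
    f1: float
    precision: float
    recall: float


@dataclass
class RiskModel:
    model_kind: str  # {"logistic", "small_mlp"}
    pipeline: Pipeline
    feature_names: tuple[str, ...]
    training_meta: TrainingMeta = field(repr=False, default=None)


def _make_pipeline(kind: str, seed: int) -> Pipeline:
    if kind == "logistic":
        clf = LogisticRegression(
            class_weight="balanced", max_iter=2000, random_state=seed
        )
    elif kind == "small_mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=(16,),
            max_iter=2000,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return X
    return np.vstack([fv.values if isinstance(fv, FeatureVector) else fv for fv in X])


def train_risk_model(
    X, y, kind: str = "logistic", seed: int = 0
) -> RiskModel:
    """Fit the stand-in risk classifier on a labelled cohort.

    ``X``: (n, 74) matrix or list of FeatureVectors; ``y``: labels in
    {"low", "high"} (or 0/1).  Held-out metrics come from a stratified
    80/20 split keyed on ``seed``; the returned model is the one fitted on
    the 80% training portion, so the reported metrics describe it exactly.
    """
    X = _as_matrix(X)
    y = np.asarray([LABELS[v] if isinstance(v, (int, np.integer)) else v for v in y])
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes = set(y)
    if classes != {"low", "high"}:
        raise ValueError(f"cohort must contain both classes, got {sorted(classes)}")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=seed
    )
    pipe = _make_pipeline(kind, seed)
    pipe.fit(X_tr, y_tr)
    pred = pipe.predict(X_te)
    meta = TrainingMeta(
        seed=seed,
        n_low=int(np.sum(y == "low")),
        n_high=int(np.sum(y == "high")),
        f1=float(f1_score(y_te, pred, pos_label="high")),
        precision=float(precision_score(y_te, pred, pos_label="high", zero_division=0)),
        recall=float(recall_score(y_te, pred, pos_label="high")),
    )
    return RiskModel(
        model_kind=kind,
        pipeline=pipe,
        feature_names=FEATURE_NAMES,
        training_meta=meta,
    )


class _FrozenPipeline:
    """Deserialised model: standardise then score, no sklearn state needed.

    Supports the two kinds this package trains: a logistic layer, or one
    ReLU hidden layer followed by a logistic output.
    """

    def __init__(self, kind: str, payload: dict):
        self.kind = kind
        self.mean = np.asarray(payload["scaler_mean"], dtype=float)
        self.scale = np.asarray(payload["scaler_scale"], dtype=float)
        self.classes_ = np.asarray(payload["classes"])
        self.weights = [np.asarray(w, dtype=float) for w in payload["weights"]]
        self.biases = [np.asarray(b, dtype=float) for b in payload["biases"]]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = (np.asarray(X, dtype=float) - self.mean) / self.scale
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            z = np.maximum(z @ w + b, 0.0)  # ReLU hidden layers
        logit = (z @ self.weights[-1] + self.biases[-1]).ravel()
        p1 = 1.0 / (1.0 + np.exp(-logit))
        return np.column_stack([1.0 - p1, p1])


def save_model(model: RiskModel, path) -> None:
    """Serialise a trained model (architecture + weights) to JSON."""
    import json
    from pathlib import Path

    scaler = model.pipeline.named_steps["scale"]
    clf = model.pipeline.named_steps["clf"]
    if model.model_kind == "logistic":
        weights = [clf.coef_.T.tolist()]
        biases = [clf.intercept_.tolist()]
    else:  # small_mlp
        weights = [w.tolist() for w in clf.coefs_]
        biases = [b.tolist() for b in clf.intercepts_]
    meta = model.training_meta
    payload = {
        "schema_version": "1",
        "model_kind": model.model_kind,
        "feature_names": list(model.feature_names),
        "scaler_mean": scaler.mean_.tolist(),
        "scaler_scale": scaler.scale_.tolist(),
        "classes": list(clf.classes_),
        "weights": weights,
        "biases": biases,
        "training_meta": {
            "seed": meta.seed,
            "n_low": meta.n_low,
            "n_high": meta.n_high,
            "f1": meta.f1,
            "precision": meta.precision,
            "recall": meta.recall,
        },
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def load_model(path) -> RiskModel:
    """Load a model saved by :func:`save_model`; prediction-only."""
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    meta = TrainingMeta(**payload["training_meta"])
    return RiskModel(
        model_kind=payload["model_kind"],
        pipeline=_FrozenPipeline(payload["model_kind"], payload),
        feature_names=tuple(payload["feature_names"]),
        training_meta=meta,
    )


def predict_risk(model: RiskModel, fv: FeatureVector | np.ndarray) -> tuple[str, float]:
    """Predict ("low"|"high", score) for one exam; score is P(high) in [0,1]."""
    x = fv.values if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=float)
    if x.shape != (len(model.feature_names),):
        raise ValueError(
            f"feature vector length {x.shape} does not match schema "
            f"({len(model.feature_names)} features)"
        )
    proba = model.pipeline.predict_proba(x.reshape(1, -1))[0]
    idx_high = list(model.pipeline.classes_).index("high")
    score = float(proba[idx_high])
    return ("high" if score >= 0.5 else "low"), score
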