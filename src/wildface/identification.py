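"""Closed-set individual identification: one-vs-rest linear SVM on embeddings."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .datatypes import Embedding, IdentityPrediction

__all__ = ["ClassifierConfig", "ClassifierModel", "train_classifier", "predict_identity"]


@dataclass(frozen=True)
class ClassifierConfig:
    C: float = 1.0
    seed: int = 0


@dataclass
class ClassifierModel:
    labels: list[str]  # sorted lexicographically
    weights: np.ndarray  # (n_classes, D)
    biases: np.ndarray  # (n_classes,)
    config: ClassifierConfig = field(default_factory=ClassifierConfig)
    version: int = 1

    @property
    def D(self) -> int:
        return self.weights.shape[1]


def train_classifier(
    embeddings: Sequence[Embedding], config: ClassifierConfig | None = None
) -> ClassifierModel:
    """One-vs-rest max-margin fit; deterministic given the seed."""
    config = config or ClassifierConfig()
    labels = [e.identity for e in embeddings]
    if any(l is None for l in labels):
        raise ValueError("all embeddings must carry an identity label")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 identities to train a closed-set classifier")
    X = np.vstack([e.vector for e in embeddings])
    y = np.array(labels)
    svc = LinearSVC(C=config.C, random_state=config.seed, max_iter=20000, tol=1e-5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svc.fit(X, y)
    # sklearn orders string classes lexicographically already
    classes_sorted = list(svc.classes_)
    if len(classes) == 2:
        # binary LinearSVC yields one hyperplane; expand to per-class scores
        weights = np.vstack([-svc.coef_[0], svc.coef_[0]])
        biases = np.array([-svc.intercept_[0], svc.intercept_[0]])
    else:
        weights = svc.coef_.copy()
        biases = svc.intercept_.copy()
    return ClassifierModel(labels=classes_sorted, weights=weights, biases=biases, config=config)


def predict_identity(model: ClassifierModel, e: Embedding | np.ndarray) -> IdentityPrediction:
    """Argmax of per-class scores; ties break to the lexicographically first label."""
    v = e.vector if isinstance(e, Embedding) else np.asarray(e, dtype=float)
    if v.shape != (model.D,):
        raise ValueError(f"dimension mismatch: embedding {v.shape}, model expects ({model.D},)")
    scores = model.weights @ v + model.biases
    best = int(np.argmax(scores))  # labels sorted, argmax takes first max
    ranked = np.sort(scores)[::-1]
    margin = float(ranked[0] - ranked[1]) if len(ranked) > 1 else float(ranked[0])
    return IdentityPrediction(
        label=model.labels[best],
        margin=margin,
        scores={lab: float(s) for lab, s in zip(model.labels, scores)},
    )
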