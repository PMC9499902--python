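"""End-to-end orchestration: train all four stages, evaluate them together.

The pipeline mirrors the four-stage architecture: face detection, landmark
prediction, eye-aligned chipping, metric embedding, and closed-set SVM
identification.  ``train_pipeline`` fits every trainable stage on one
manifest; ``evaluate_pipeline`` reproduces the full testing methodology on
a held-out manifest: detector precision/recall/AP, shape-predictor
normalized error, verification on balanced chip pairs, closed-set
identification on golden chips, and the cumulative end-to-end accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import evaluation
from .chipping import ChipSpec, extract_chip
from .datatypes import DatasetManifest, FaceChip
from .detection import DetectorConfig, DetectorModel, HogParams, detect_faces, train_detector
from .embedding import (
    EmbedderConfig,
    EmbedderModel,
    EmbedRecipe,
    embed_chip,
    featurize_chips,
    train_embedder_features,
)
from .identification import ClassifierConfig, ClassifierModel, predict_identity, train_classifier
from .landmarks import ShapeConfig, ShapeModel, predict_landmarks, train_shape_predictor
from .manifest import load_image

__all__ = ["PipelineModels", "golden_chips", "train_pipeline", "evaluate_pipeline"]


@dataclass
class PipelineModels:
    detector: DetectorModel
    shape: ShapeModel
    chip_spec: ChipSpec
    embedder: EmbedderModel
    classifier: ClassifierModel


def _pixels(img, base_dir: str):
    return img.pixels if img.pixels is not None else load_image(img.source_id, base_dir)


def golden_chips(manifest: DatasetManifest, chip_spec: ChipSpec | None = None) -> list[FaceChip]:
    """Eye-aligned chips cut at the ground-truth landmarks (one per annotation)."""
    chip_spec = chip_spec or ChipSpec()
    chips = []
    for img in manifest.images:
        pixels = _pixels(img, manifest.base_dir)
        for ann in img.annotations:
            chips.append(
                extract_chip(pixels, ann.landmarks, chip_spec, identity=ann.identity, source_id=img.source_id)
            )
    return chips


def train_pipeline(
    train: DatasetManifest,
    seed: int = 0,
    hog_params: HogParams | None = None,
    detector_config: DetectorConfig | None = None,
    shape_config: ShapeConfig | None = None,
    embed_config: EmbedderConfig | None = None,
    chip_spec: ChipSpec | None = None,
    recipe: EmbedRecipe | None = None,
) -> PipelineModels:
    """Fit detector, shape predictor, embedder and classifier on one manifest."""
    chip_spec = chip_spec or ChipSpec()
    recipe = recipe or EmbedRecipe()
    detector = train_detector(train, hog_params, detector_config or DetectorConfig(seed=seed))
    shape = train_shape_predictor(train, shape_config or ShapeConfig(seed=seed))
    chips = golden_chips(train, chip_spec)
    labels = [c.identity for c in chips]
    X = featurize_chips(chips, recipe)
    embedder = train_embedder_features(X, labels, embed_config or EmbedderConfig(seed=seed), recipe)
    emb = embedder.embed_features(X)
    from .datatypes import Embedding

    embeddings = [Embedding(vector=v, identity=l) for v, l in zip(emb, labels)]
    classifier = train_classifier(embeddings, ClassifierConfig(seed=seed))
    return PipelineModels(detector=detector, shape=shape, chip_spec=chip_spec, embedder=embedder, classifier=classifier)


def evaluate_pipeline(
    models: PipelineModels,
    test: DatasetManifest,
    seed: int = 0,
    n_pairs_per_class: int = 230,
    detection_score_threshold: Optional[float] = None,
) -> dict:
    """The complete held-out report, as a JSON-serializable dict."""
    # precision/recall at the operating threshold; AP from the full ranked
    # list (score threshold dropped), as the PR curve is threshold-free
    gt_per_image = [img.annotations for img in test.images]
    ranked_per_image = []
    operating_per_image = []
    strata = []
    thr = models.detector.score_threshold if detection_score_threshold is None else detection_score_threshold
    for img in test.images:
        pixels = _pixels(img, test.base_dir)
        ranked = detect_faces(models.detector, pixels, score_threshold=-1.0)
        ranked_per_image.append(ranked)
        operating_per_image.append([d for d in ranked if d.score >= thr])
        strata.append(img.annotations[0].species if img.annotations and img.annotations[0].species else "")
    det_eval = evaluation.evaluate_detections(gt_per_image, operating_per_image, 0.5, strata=strata)
    det_eval.average_precision = evaluation.evaluate_detections(
        gt_per_image, ranked_per_image, 0.5
    ).average_precision

    # shape predictor in isolation: golden boxes in, normalized error out
    lm_pred = []
    lm_gt = []
    for img in test.images:
        pixels = _pixels(img, test.base_dir)
        for ann in img.annotations:
            lm_pred.append(predict_landmarks(models.shape, pixels, ann.box))
            lm_gt.append(ann)
    lm_eval = evaluation.landmark_error(lm_pred, lm_gt)

    # verification on golden test chips at the operating threshold
    chips = golden_chips(test, models.chip_spec)
    labels = [c.identity for c in chips]
    X = featurize_chips(chips, models.embedder.recipe)
    emb = models.embedder.embed_features(X)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        pairs = evaluation.build_pair_set(labels, n_pairs_per_class, seed=seed)
    dists = [float(np.linalg.norm(emb[p.a] - emb[p.b])) for p in pairs]
    ver_eval = evaluation.verification_metrics(pairs, dists, models.embedder.tau)
    roc = evaluation.roc_points(pairs, dists)

    # closed-set identification on golden chips (no cumulative error)
    preds = [predict_identity(models.classifier, v) for v in emb]
    id_ratio, id_pct = evaluation.identification_accuracy(preds, labels)

    e2e = evaluation.end_to_end_evaluate(
        models.detector, models.shape, models.chip_spec, models.embedder, models.classifier, test
    )

    return {
        "seed": seed,
        "detection": det_eval.to_dict(),
        "landmarks": lm_eval.to_dict(),
        "verification_golden": ver_eval.to_dict(),
        "roc_auc": evaluation.roc_auc(roc),
        "identification_golden": {
            "accuracy": id_ratio,
            "accuracy_pct": id_pct,
            "n_correct": int(round(id_ratio * len(labels))),
            "n_total": len(labels),
        },
        "end_to_end": e2e.to_dict(),
    }
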