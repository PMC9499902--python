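"""The complete testing methodology for the identification pipeline.

Covers detection scoring (greedy matching at an IoU threshold, precision,
recall, interpolated average precision), normalized landmark error,
verification pair construction and metrics (balanced accuracy, TPR/TNR,
F1, ROC), the two fivefold cross-validation regimes (folds across chips
versus folds by identity), closed-set identification accuracy, and the
cumulative end-to-end accounting from input image to identity.

Percentages are reported to one decimal place, rounding half up.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence

import numpy as np

from .datatypes import Box, ChipPair, Detection, FaceAnnotation, IdentityPrediction
from .detection import iou

__all__ = [
    "percent",
    "MatchAssignment",
    "DetectionEval",
    "LandmarkEval",
    "VerificationEval",
    "FoldEval",
    "EndToEndEval",
    "match_detections",
    "detection_metrics",
    "interpolated_ap",
    "evaluate_detections",
    "landmark_error",
    "build_pair_set",
    "verification_metrics",
    "roc_points",
    "roc_auc",
    "make_folds",
    "crossval_verification",
    "identification_accuracy",
    "end_to_end_evaluate",
]


def percent(ratio: float) -> float:
    """Ratio -> percentage with one decimal, round half up (e.g. 104/121 -> 86.0)."""
    return float(Decimal(repr(ratio * 100.0)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


@dataclass
class MatchAssignment:
    """TP/FP labels per detection (score order) and the FN count."""

    det_labels: list[bool]  # True = TP, aligned with det_scores
    det_scores: list[float]
    matched_gt: list[Optional[int]]  # gt index claimed by each detection
    n_gt: int

    @property
    def tp(self) -> int:
        return sum(self.det_labels)

    @property
    def fp(self) -> int:
        return len(self.det_labels) - self.tp

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp


def match_detections(
    gt: Sequence[FaceAnnotation | Box],
    pred: Sequence[Detection],
    iou_threshold: float = 0.5,
) -> MatchAssignment:
    """Greedy assignment: descending score, each detection claims the
    unmatched ground-truth box of highest IoU if that IoU reaches the
    threshold; IoU ties break to the earlier ground-truth entry."""
    gt_boxes = [g.box if isinstance(g, FaceAnnotation) else g for g in gt]
    order = sorted(range(len(pred)), key=lambda i: -pred[i].score)
    claimed = [False] * len(gt_boxes)
    det_labels: list[bool] = []
    det_scores: list[float] = []
    matched: list[Optional[int]] = []
    for i in order:
        det = pred[i]
        best_j, best_iou = None, 0.0
        for j, gbox in enumerate(gt_boxes):
            if claimed[j]:
                continue
            v = iou(det.box, gbox)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        det_scores.append(det.score)
        if best_j is None:
            det_labels.append(False)
            matched.append(None)
        else:
            claimed[best_j] = True
            det_labels.append(True)
            matched.append(best_j)
    return MatchAssignment(det_labels=det_labels, det_scores=det_scores, matched_gt=matched, n_gt=len(gt_boxes))


def detection_metrics(assignment: MatchAssignment) -> tuple[float, float]:
    """(precision, recall); precision defaults to 1.0 when nothing was detected."""
    tp, fp, fn = assignment.tp, assignment.fp, assignment.fn
    precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return precision, recall


def interpolated_ap(labels: Sequence[bool], scores: Sequence[float], n_gt: int) -> float:
    """Interpolated average precision: area under the precision-recall
    curve with the precision envelope taken as a running maximum from high
    recall to low; no credit beyond the highest achieved recall."""
    if n_gt < 1:
        raise ValueError("n_gt must be >= 1")
    if len(labels) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    lab = np.asarray(labels, dtype=bool)[order]
    tp_cum = np.cumsum(lab)
    fp_cum = np.cumsum(~lab)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # running-max envelope from the high-recall end
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, envelope):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


@dataclass
class DetectionEval:
    n_gt: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    average_precision: float
    per_stratum: dict[str, "DetectionEval"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_gt": self.n_gt,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "average_precision": self.average_precision,
        }
        if self.per_stratum:
            d["per_stratum"] = {k: v.to_dict() for k, v in self.per_stratum.items()}
        return d


def evaluate_detections(
    gt_per_image: Sequence[Sequence[FaceAnnotation | Box]],
    pred_per_image: Sequence[Sequence[Detection]],
    iou_threshold: float = 0.5,
    strata: Optional[Sequence[str]] = None,
) -> DetectionEval:
    """Pool per-image assignments into dataset-level precision/recall/AP."""
    labels: list[bool] = []
    scores: list[float] = []
    n_gt = 0
    for gt, pred in zip(gt_per_image, pred_per_image):
        a = match_detections(gt, pred, iou_threshold)
        labels.extend(a.det_labels)
        scores.extend(a.det_scores)
        n_gt += a.n_gt
    tp = sum(labels)
    fp = len(labels) - tp
    fn = n_gt - tp
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / n_gt if n_gt else 0.0
    ap = interpolated_ap(labels, scores, n_gt) if n_gt else 0.0
    result = DetectionEval(n_gt=n_gt, tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, average_precision=ap)
    if strata is not None:
        for name in sorted(set(strata)):
            idx = [i for i, s in enumerate(strata) if s == name]
            result.per_stratum[name] = evaluate_detections(
                [gt_per_image[i] for i in idx], [pred_per_image[i] for i in idx], iou_threshold
            )
    return result


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------


@dataclass
class LandmarkEval:
    distances: list[float]
    mean: float
    sd: float
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "n": len(self.distances), "n_excluded": self.n_excluded}


def landmark_error(
    pred: Sequence[dict], gt: Sequence[FaceAnnotation]
) -> LandmarkEval:
    """Per-face mean landmark error normalized by the ground-truth
    inter-ocular distance; mean and sample SD over faces.  Faces whose
    ground-truth inter-ocular distance is zero are excluded with a
    warning."""
    distances: list[float] = []
    excluded = 0
    for p, g in zip(pred, gt):
        iod = g.interocular_distance()
        if iod is None or iod <= 0:
            excluded += 1
            continue
        landmarks = p.landmarks if hasattr(p, "landmarks") else p
        errs = [landmarks[name].distance_to(g.landmarks[name]) for name in g.landmarks]
        distances.append(float(np.mean(errs)) / iod)
    if excluded:
        warnings.warn(f"{excluded} face(s) excluded: zero inter-ocular distance")
    if not distances:
        return LandmarkEval(distances=[], mean=float("nan"), sd=float("nan"), n_excluded=excluded)
    mean = float(np.mean(distances))
    sd = float(np.std(distances, ddof=1)) if len(distances) > 1 else 0.0
    return LandmarkEval(distances=distances, mean=mean, sd=sd, n_excluded=excluded)


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------


def build_pair_set(
    labels: Sequence[str],
    n_per_class: int,
    seed: int = 0,
    exhaustive_matching: bool = False,
) -> list[ChipPair]:
    """Balanced test pairs: ``n_per_class`` matching and the same number of
    non-matching unordered pairs, all unique, no self-pairs, sampled
    without replacement.  If fewer matching pairs exist than requested,
    all of them are used (with a warning) and the non-matching count
    follows suit.  ``exhaustive_matching`` takes every possible matching
    pair instead of sampling."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 identities to build non-matching pairs")
    match_all: list[tuple[int, int]] = []
    for ident in np.unique(labels):
        idx = np.nonzero(labels == ident)[0]
        match_all.extend((int(a), int(b)) for a, b in itertools.combinations(idx, 2))
    if not match_all:
        raise ValueError("no matching pairs possible: every identity has a single chip")
    if exhaustive_matching or len(match_all) <= n_per_class:
        if not exhaustive_matching and len(match_all) < n_per_class:
            warnings.warn(
                f"only {len(match_all)} matching pairs available (requested {n_per_class}); using all"
            )
        match = match_all
    else:
        sel = rng.choice(len(match_all), size=n_per_class, replace=False)
        match = [match_all[int(i)] for i in np.sort(sel)]

    non_all: list[tuple[int, int]] = [
        (int(a), int(b))
        for a, b in itertools.combinations(range(len(labels)), 2)
        if labels[a] != labels[b]
    ]
    n_non = min(len(match), len(non_all)) if exhaustive_matching else min(len(match), len(non_all))
    if len(non_all) < len(match):
        warnings.warn(f"only {len(non_all)} non-matching pairs available; pair set is unbalanced")
    sel = rng.choice(len(non_all), size=n_non, replace=False)
    non = [non_all[int(i)] for i in np.sort(sel)]
    return [ChipPair(a, b, True) for a, b in match] + [ChipPair(a, b, False) for a, b in non]


@dataclass
class VerificationEval:
    n_match: int
    n_non: int
    tpr: float
    tnr: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "n_match": self.n_match,
            "n_non": self.n_non,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "threshold": self.threshold,
        }


def verification_metrics(
    pairs: Sequence[ChipPair], distances: Sequence[float], threshold: float
) -> VerificationEval:
    """Predict 'match' iff distance <= threshold; accuracy is the
    ratio-weighted combination TPR x positive_ratio + TNR x negative_ratio
    (0.5/0.5 for the balanced sets built here).  Precision/recall/F1 are
    over the matching class."""
    if len(pairs) != len(distances):
        raise ValueError("one distance per pair required")
    d = np.asarray(distances, dtype=float)
    is_match = np.array([p.is_match for p in pairs])
    pred_match = d <= threshold
    n_match = int(is_match.sum())
    n_non = int((~is_match).sum())
    tp = int(np.sum(pred_match & is_match))
    tn = int(np.sum(~pred_match & ~is_match))
    fp = int(np.sum(pred_match & ~is_match))
    tpr = tp / n_match if n_match else 0.0
    tnr = tn / n_non if n_non else 0.0
    pos_ratio = n_match / len(pairs)
    accuracy = tpr * pos_ratio + tnr * (1.0 - pos_ratio)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tpr
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return VerificationEval(
        n_match=n_match,
        n_non=n_non,
        tpr=tpr,
        tnr=tnr,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        threshold=threshold,
    )


def roc_points(pairs: Sequence[ChipPair], distances: Sequence[float]) -> list[tuple[float, float, float]]:
    """(FPR, TPR, threshold) per distinct threshold, from (0,0) to (1,1);
    TPR is nondecreasing along the curve."""
    d = np.asarray(distances, dtype=float)
    is_match = np.array([p.is_match for p in pairs])
    n_match = int(is_match.sum())
    n_non = len(pairs) - n_match
    if n_match == 0 or n_non == 0:
        raise ValueError("need at least one pair of each class")
    points = [(0.0, 0.0, float("-inf"))]
    for t in np.unique(d):
        pred = d <= t
        tpr = float(np.sum(pred & is_match)) / n_match
        fpr = float(np.sum(pred & ~is_match)) / n_non
        points.append((fpr, tpr, float(t)))
    if points[-1][:2] != (1.0, 1.0):
        points.append((1.0, 1.0, float("inf")))
    return points


def roc_auc(points: Sequence[tuple[float, float, float]]) -> float:
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def make_folds(
    labels: Sequence[str], k: int, regime: str, seed: int = 0
) -> list[np.ndarray]:
    """Partition chip indices into k folds.

    ``by_chip``: identity-stratified random partition, so each
    individual's chips spread across folds where possible.  ``by_id``:
    identities are partitioned and chips follow their identity, so no
    individual ever spans folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if regime == "by_chip":
        if len(labels) < k:
            raise ValueError(f"by_chip requires >= {k} chips")
        offset = 0
        for ident in np.unique(labels):
            idx = np.nonzero(labels == ident)[0]
            idx = idx[rng.permutation(len(idx))]
            for i, chip in enumerate(idx):
                folds[(offset + i) % k].append(int(chip))
            offset += len(idx)
    elif regime == "by_id":
        idents = np.unique(labels)
        if len(idents) < k:
            raise ValueError(f"by_id requires >= {k} identities, got {len(idents)}")
        idents = idents[rng.permutation(len(idents))]
        for part_i, part in enumerate(np.array_split(idents, k)):
            chosen = set(part.tolist())
            folds[part_i].extend(int(i) for i in np.nonzero(np.isin(labels, list(chosen)))[0])
    else:
        raise ValueError(f"unknown regime {regime!r} (use 'by_chip' or 'by_id')")
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


@dataclass
class FoldEval:
    regime: str
    per_fold: list[VerificationEval]
    mean_test_n: float
    sd_test_n: float
    mean_accuracy: float
    sd_accuracy: float
    mean_tpr: float
    sd_tpr: float
    mean_tnr: float
    sd_tnr: float
    mean_f1: float
    sd_f1: float

    def to_dict(self) -> dict:
        return {
            "regime": self.regime,
            "mean_test_n": self.mean_test_n,
            "sd_test_n": self.sd_test_n,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_tpr": self.mean_tpr,
            "sd_tpr": self.sd_tpr,
            "mean_tnr": self.mean_tnr,
            "sd_tnr": self.sd_tnr,
            "mean_f1": self.mean_f1,
            "sd_f1": self.sd_f1,
            "folds": [f.to_dict() for f in self.per_fold],
        }


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0


def crossval_verification(
    features: np.ndarray,
    labels: Sequence[str],
    k: int,
    regime: str,
    seed: int = 0,
    n_pairs_per_class: int = 230,
    train_fn: Optional[Callable] = None,
) -> FoldEval:
    """k-fold verification: per fold, train the embedder on the remaining
    folds, build a balanced pair set from the held-out fold, and score it
    at the model's operating threshold.  Mean +/- sample SD across folds.

    ``train_fn(X, labels, seed)`` must return an object with
    ``embed_features`` and ``tau``; the default trains the package
    embedder on precomputed descriptors."""
    from .embedding import EmbedderConfig, train_embedder_features

    if train_fn is None:
        # the operating threshold is tuned on training pairs per fold, so the
        # held-out fold never informs its own operating point
        def train_fn(X, labs, s):  # noqa: F811
            return train_embedder_features(X, labs, EmbedderConfig(seed=s, tune_tau=True))

    labels = np.asarray(labels)
    folds = make_folds(labels, k, regime, seed)
    evals: list[VerificationEval] = []
    test_ns: list[int] = []
    for fold_i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(labels)), test_idx)
        test_labels = labels[test_idx]
        counts = {l: int(np.sum(test_labels == l)) for l in np.unique(test_labels)}
        if not any(c >= 2 for c in counts.values()) or len(counts) < 2:
            warnings.warn(f"fold {fold_i}: no matching pairs possible; skipped")
            continue
        model = train_fn(features[train_idx], labels[train_idx], seed + fold_i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairs = build_pair_set(test_labels, n_pairs_per_class, seed=seed + 100 + fold_i)
        emb = model.embed_features(features[test_idx])
        dists = [float(np.linalg.norm(emb[p.a] - emb[p.b])) for p in pairs]
        evals.append(verification_metrics(pairs, dists, model.tau))
        test_ns.append(len(test_idx))
    if not evals:
        raise ValueError("no fold produced any verification pairs")
    m_n, s_n = _mean_sd(test_ns)
    m_a, s_a = _mean_sd([e.accuracy for e in evals])
    m_tpr, s_tpr = _mean_sd([e.tpr for e in evals])
    m_tnr, s_tnr = _mean_sd([e.tnr for e in evals])
    m_f1, s_f1 = _mean_sd([e.f1 for e in evals])
    return FoldEval(
        regime=regime,
        per_fold=evals,
        mean_test_n=m_n,
        sd_test_n=s_n,
        mean_accuracy=m_a,
        sd_accuracy=s_a,
        mean_tpr=m_tpr,
        sd_tpr=s_tpr,
        mean_tnr=m_tnr,
        sd_tnr=s_tnr,
        mean_f1=m_f1,
        sd_f1=s_f1,
    )


# ---------------------------------------------------------------------------
# identification + end-to-end
# ---------------------------------------------------------------------------


def identification_accuracy(
    predictions: Sequence[IdentityPrediction | str], truth: Sequence[str]
) -> tuple[float, float]:
    """(ratio, percent): correct predictions / total predictions."""
    if len(predictions) == 0:
        raise ValueError("no predictions to score")
    if len(predictions) != len(truth):
        raise ValueError("prediction and truth lists must align")
    pred_labels = [p.label if isinstance(p, IdentityPrediction) else p for p in predictions]
    correct = sum(p == t for p, t in zip(pred_labels, truth))
    ratio = correct / len(predictions)
    return ratio, percent(ratio)


@dataclass
class EndToEndEval:
    n_images: int
    faces_detected: int
    faces_missed: int
    erroneous_detections: int
    correct_ids: int
    accuracy_over_images: float
    accuracy_over_detected: float
    policy: str = "exclude-erroneous"

    @property
    def total_detections(self) -> int:
        return self.faces_detected + self.erroneous_detections

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "faces_detected": self.faces_detected,
            "faces_missed": self.faces_missed,
            "erroneous_detections": self.erroneous_detections,
            "total_detections": self.total_detections,
            "correct_ids": self.correct_ids,
            "accuracy_over_images": self.accuracy_over_images,
            "accuracy_over_images_pct": percent(self.accuracy_over_images),
            "accuracy_over_detected": self.accuracy_over_detected,
            "accuracy_over_detected_pct": percent(self.accuracy_over_detected),
            "policy": self.policy,
        }


def end_to_end_evaluate(
    detector,
    shape_model,
    chip_spec,
    embedder,
    classifier,
    test,
    policy: str = "exclude-erroneous",
    iou_threshold: float = 0.5,
) -> EndToEndEval:
    """Run the full pipeline image-by-image and account for cumulative error.

    Detections are matched to ground truth at the IoU threshold; unmatched
    detections are counted as erroneous and, under the default
    ``exclude-erroneous`` policy, excluded from identity scoring.
    Accuracy is reported both over all annotated faces and over correctly
    detected faces only."""
    from .chipping import extract_chip
    from .detection import detect_faces
    from .embedding import embed_chip
    from .identification import predict_identity
    from .landmarks import predict_landmarks

    n_faces = 0
    detected = 0
    erroneous = 0
    correct = 0
    for img in test.images:
        if img.pixels is None:
            from .manifest import load_image

            pixels = load_image(img.source_id, test.base_dir)
        else:
            pixels = img.pixels
        gt = img.annotations
        n_faces += len(gt)
        dets = detect_faces(detector, pixels)
        assign = match_detections(gt, dets, iou_threshold)
        detected += assign.tp
        erroneous += assign.fp
        order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
        for rank, det_i in enumerate(order):
            gt_i = assign.matched_gt[rank]
            if gt_i is None:
                if policy == "exclude-erroneous":
                    continue
                gt_identity = None
            else:
                gt_identity = gt[gt_i].identity
            pred_lm = predict_landmarks(shape_model, pixels, dets[det_i].box)
            chip = extract_chip(pixels, pred_lm.landmarks, chip_spec, source_id=img.source_id)
            emb = embed_chip(embedder, chip)
            pred = predict_identity(classifier, emb)
            if gt_identity is not None and pred.label == gt_identity:
                correct += 1
    return EndToEndEval(
        n_images=n_faces,
        faces_detected=detected,
        faces_missed=n_faces - detected,
        erroneous_detections=erroneous,
        correct_ids=correct,
        accuracy_over_images=correct / n_faces if n_faces else 0.0,
        accuracy_over_detected=correct / detected if detected else 0.0,
        policy=policy,
    )
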