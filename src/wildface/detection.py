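"""Trainable single-class sliding-window face detector.

A gradient-histogram feature pyramid scored by a max-margin linear model
(Dalal–Triggs lineage): ground-truth boxes warped to a fixed window give
positives, random plus hard-mined windows give negatives, and a linear SVM
separates them.  Detection slides the window over every pyramid level,
thresholds the score, and applies greedy non-maximum suppression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import rescale, resize
from sklearn.svm import LinearSVC

from .datatypes import AnnotatedImage, Box, DatasetManifest, Detection
from .hog import CELLS_PER_BLOCK, HogParams, extract_hog, window_feature_length, window_features

__all__ = [
    "HogParams",
    "DetectorConfig",
    "DetectorModel",
    "iou",
    "nms",
    "train_detector",
    "detect_faces",
]


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    ix = min(a.right, b.right) - max(a.left, b.left)
    iy = min(a.bottom, b.bottom) - max(a.top, b.top)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return float(min(1.0, inter / (a.area + b.area - inter)))


def nms(detections: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression.

    Detections are visited in descending score (ties broken by left, then
    top); a detection survives iff its IoU with every higher-ranked
    survivor is strictly below ``iou_threshold``.
    """
    ordered = sorted(detections, key=lambda d: (-d.score, d.box.left, d.box.top))
    kept: list[Detection] = []
    for det in ordered:
        if all(iou(det.box, k.box) < iou_threshold for k in kept):
            kept.append(det)
    return kept


@dataclass(frozen=True)
class DetectorConfig:
    """Training knobs; defaults are the package's standard desk-scale recipe."""

    C: float = 1.0
    hard_negative_rounds: int = 3
    negatives_per_image: int = 6
    max_hard_negatives_per_image: int = 10
    seed: int = 0


@dataclass
class DetectorModel:
    """Linear scorer over window HOG features plus pyramid/NMS settings."""

    hog_params: HogParams
    weights: np.ndarray
    bias: float
    pyramid_scale: float = 5.0 / 6.0
    nms_iou: float = 0.5
    score_threshold: float = 0.5
    version: int = 1

    def __post_init__(self) -> None:
        expected = window_feature_length(self.hog_params)
        if self.weights.shape != (expected,):
            raise ValueError(f"weight vector length {self.weights.shape} != feature length {expected}")


def _square_box(box: Box) -> Box:
    side = max(box.width, box.height)
    c = box.center
    return Box(c.x - side / 2.0, c.y - side / 2.0, side, side)


def _crop_window(image: np.ndarray, box: Box, window_px: tuple[int, int]) -> np.ndarray:
    """Crop a (possibly out-of-bounds) box with edge replication, resize to window."""
    h, w = image.shape
    sq = _square_box(box)
    x0, y0 = int(np.floor(sq.left)), int(np.floor(sq.top))
    x1, y1 = int(np.ceil(sq.right)), int(np.ceil(sq.bottom))
    pad_l, pad_t = max(0, -x0), max(0, -y0)
    pad_r, pad_b = max(0, x1 - w), max(0, y1 - h)
    crop = image[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)]
    if pad_l or pad_t or pad_r or pad_b:
        crop = np.pad(crop, ((pad_t, pad_b), (pad_l, pad_r)), mode="edge")
    return resize(crop, window_px, order=1, mode="edge", anti_aliasing=True)


def _require_pixels(img: AnnotatedImage, base_dir: str = "") -> np.ndarray:
    if img.pixels is None:
        from .manifest import load_image

        return load_image(img.source_id, base_dir)
    return img.pixels


def _pyramid_levels(shape: tuple[int, int], model_scale: float, window_px: tuple[int, int], max_levels: int = 12):
    """Yield (scale, ) factors until the level is smaller than the window."""
    s = 1.0
    for _ in range(max_levels):
        if shape[0] * s < window_px[0] or shape[1] * s < window_px[1]:
            return
        yield s
        s *= model_scale


def _scan_image(
    image: np.ndarray,
    hog_params: HogParams,
    weights: np.ndarray,
    bias: float,
    pyramid_scale: float,
    score_threshold: float,
) -> list[Detection]:
    """Score every window of every pyramid level; no NMS."""
    cell = hog_params.cell_size
    win_r, win_c = hog_params.window_px
    out: list[Detection] = []
    for s in _pyramid_levels(image.shape, pyramid_scale, (win_r, win_c)):
        level = image if s == 1.0 else rescale(image, s, order=1, mode="edge", anti_aliasing=True)
        grid = extract_hog(level, hog_params)
        feats = window_features(grid, hog_params)
        if feats.size == 0:
            continue
        scores = feats @ weights + bias
        ii, jj = np.nonzero(scores >= score_threshold)
        for i, j in zip(ii.tolist(), jj.tolist()):
            box = Box(j * cell / s, i * cell / s, win_c / s, win_r / s)
            out.append(Detection(box=box, score=float(scores[i, j])))
    return out


def _random_negative_windows(
    image: np.ndarray,
    gt_boxes: list[Box],
    hog_params: HogParams,
    n: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    h, w = image.shape
    win = hog_params.window_px[0]
    feats = []
    for _ in range(n * 4):
        if len(feats) >= n:
            break
        side = rng.uniform(win, min(h, w))
        x = rng.uniform(0, w - side)
        y = rng.uniform(0, h - side)
        cand = Box(x, y, side, side)
        if all(iou(cand, g) <= 0.3 for g in gt_boxes):
            crop = _crop_window(image, cand, hog_params.window_px)
            feats.append(extract_hog(crop, hog_params).ravel())
    return feats


def train_detector(
    train: DatasetManifest,
    params: HogParams | None = None,
    config: DetectorConfig | None = None,
) -> DetectorModel:
    """Fit the max-margin window scorer with hard-negative mining.

    Positives are ground-truth boxes warped to the window; initial
    negatives are random face-free windows; subsequent rounds add false
    positives mined by running the current model over the training images
    with ground-truth regions excluded.  Deterministic given
    ``config.seed``.
    """
    params = params or HogParams()
    config = config or DetectorConfig()
    rng = np.random.default_rng(config.seed)

    positives: list[np.ndarray] = []
    negatives: list[np.ndarray] = []
    images: list[tuple[np.ndarray, list[Box]]] = []
    for img in train.images:
        pixels = _require_pixels(img, train.base_dir)
        gt = [ann.box for ann in img.annotations]
        images.append((pixels, gt))
        for box in gt:
            crop = _crop_window(pixels, box, params.window_px)
            positives.append(extract_hog(crop, params).ravel())
        negatives.extend(_random_negative_windows(pixels, gt, params, config.negatives_per_image, rng))

    if not positives:
        raise ValueError("no positive boxes in the training manifest")
    if not negatives:
        raise ValueError("could not mine any negative windows (images saturated with faces?)")

    def fit(pos: list[np.ndarray], neg: list[np.ndarray]) -> tuple[np.ndarray, float]:
        X = np.vstack([np.asarray(pos), np.asarray(neg)])
        y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        svc = LinearSVC(C=config.C, random_state=config.seed, max_iter=20000, tol=1e-5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svc.fit(X, y)
        return svc.coef_.ravel().copy(), float(svc.intercept_[0])

    weights, bias = fit(positives, negatives)

    for _ in range(config.hard_negative_rounds):
        new_neg: list[np.ndarray] = []
        for pixels, gt in images:
            dets = _scan_image(pixels, params, weights, bias, 5.0 / 6.0, score_threshold=-0.3)
            dets = nms(dets, 0.5)
            count = 0
            for det in dets:
                if count >= config.max_hard_negatives_per_image:
                    break
                if all(iou(det.box, g) <= 0.3 for g in gt):
                    crop = _crop_window(pixels, det.box, params.window_px)
                    new_neg.append(extract_hog(crop, params).ravel())
                    count += 1
        if not new_neg:
            break
        negatives.extend(new_neg)
        weights, bias = fit(positives, negatives)

    return DetectorModel(hog_params=params, weights=weights, bias=bias)


def detect_faces(
    model: DetectorModel,
    image: AnnotatedImage | np.ndarray,
    score_threshold: float | None = None,
) -> list[Detection]:
    """All supra-threshold windows after NMS, in original pixel coordinates.

    Returned detections are sorted by descending score; an empty list is a
    valid outcome (a missed face).
    """
    pixels = image if isinstance(image, np.ndarray) else _require_pixels(image)
    thr = model.score_threshold if score_threshold is None else score_threshold
    dets = _scan_image(pixels, model.hog_params, model.weights, model.bias, model.pyramid_scale, thr)
    dets = nms(dets, model.nms_iou)
    return sorted(dets, key=lambda d: (-d.score, d.box.left, d.box.top))
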