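"""Eye-landmark prediction: a cascade of gradient-boosted regression trees.

Within a detected face box the shape (the named landmark set, by default
the two outer eye corners) is regressed in box-normalized coordinates.
The predictor starts from the mean training shape; each cascade stage
samples a fixed table of box-relative pixel positions, forms
pixel-intensity *difference* features from random pairs of them, and fits
a stage of shallow regression trees by greedy variance-reduction splits,
boosted with shrinkage ``nu`` on the shape residual.  Because features and
shapes are box-relative, predictions are exactly covariant under joint
translation of image and box, and approximately covariant under scaling.

Training jitters the ground-truth boxes (shift and scale) so the cascade
tolerates the box noise a detector introduces at test time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from sklearn.tree import DecisionTreeRegressor

from .datatypes import AnnotatedImage, Box, DatasetManifest, Point2D

__all__ = ["ShapeConfig", "ShapeModel", "LandmarkPrediction", "train_shape_predictor", "predict_landmarks"]


@dataclass(frozen=True)
class ShapeConfig:
    cascade_depth: int = 8
    trees_per_stage: int = 40
    tree_depth: int = 3
    nu: float = 0.1  # shrinkage
    n_candidate_points: int = 120  # pixel positions sampled per stage
    n_features: int = 300  # pixel-difference features per stage
    oversample: int = 10  # jittered copies of each training face
    jitter_shift: float = 0.06  # box-relative translation jitter (sd of uniform half-range)
    jitter_scale: float = 0.10
    seed: int = 0


@dataclass
class CascadeStage:
    points: np.ndarray  # (P, 2) box-normalized sample positions
    pairs: np.ndarray  # (F, 2) indices into points
    trees: list[DecisionTreeRegressor]


@dataclass
class ShapeModel:
    config: ShapeConfig
    landmark_names: list[str]
    mean_shape: np.ndarray  # (L, 2) box-normalized
    stages: list[CascadeStage]
    version: int = 1


@dataclass
class LandmarkPrediction:
    landmarks: dict[str, Point2D]
    source_box: Box


def _sample_intensities(image: np.ndarray, boxes: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinear image intensities at box-normalized points for many boxes.

    ``boxes`` is (N, 4) as (left, top, width, height); returns (N, P).
    Out-of-image samples use edge replication.
    """
    xs = boxes[:, 0:1] + points[None, :, 0] * boxes[:, 2:3]
    ys = boxes[:, 1:2] + points[None, :, 1] * boxes[:, 3:4]
    vals = map_coordinates(image, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    return vals.reshape(boxes.shape[0], points.shape[0])


def _stage_features(image_groups, stage_points: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Difference features for all training instances, grouped by source image."""
    blocks = []
    for image, boxes in image_groups:
        inten = _sample_intensities(image, boxes, stage_points)
        blocks.append(inten[:, pairs[:, 0]] - inten[:, pairs[:, 1]])
    return np.vstack(blocks)


def train_shape_predictor(train: DatasetManifest, config: ShapeConfig | None = None) -> ShapeModel:
    """Fit the cascade on every annotation of the manifest.

    All annotations must carry the same landmark set; offenders are listed
    in the error.  Deterministic given ``config.seed``.
    """
    config = config or ShapeConfig()
    rng = np.random.default_rng(config.seed)

    names: list[str] | None = None
    offenders = []
    instances: list[tuple[int, Box, np.ndarray]] = []  # (image index, box, shape (L,2) image coords)
    images: list[np.ndarray] = []
    for img in train.images:
        if img.pixels is None:
            from .manifest import load_image

            pixels = load_image(img.source_id, train.base_dir)
        else:
            pixels = img.pixels
        img_idx = len(images)
        images.append(pixels)
        for ann in img.annotations:
            ann_names = sorted(ann.landmarks)
            if names is None:
                names = ann_names
            if ann_names != names:
                offenders.append((img.source_id, ann_names))
                continue
            shape = np.array([[ann.landmarks[n].x, ann.landmarks[n].y] for n in names])
            instances.append((img_idx, ann.box, shape))
    if offenders:
        raise ValueError(f"inconsistent landmark sets (expected {names}): {offenders}")
    if not instances:
        raise ValueError("no annotated faces in the training manifest")
    assert names is not None
    L = len(names)

    # oversample with jittered boxes; targets are box-normalized shapes
    boxes_per_image: dict[int, list[int]] = {}
    all_boxes = []
    targets = []
    for img_idx, box, shape in instances:
        for r in range(config.oversample):
            if r == 0:
                jbox = box
            else:
                ds = 1.0 + rng.uniform(-config.jitter_scale, config.jitter_scale)
                dx = rng.uniform(-config.jitter_shift, config.jitter_shift) * box.width
                dy = rng.uniform(-config.jitter_shift, config.jitter_shift) * box.height
                c = box.center
                jbox = Box(
                    c.x - box.width * ds / 2.0 + dx,
                    c.y - box.height * ds / 2.0 + dy,
                    box.width * ds,
                    box.height * ds,
                )
            t = np.empty((L, 2))
            t[:, 0] = (shape[:, 0] - jbox.left) / jbox.width
            t[:, 1] = (shape[:, 1] - jbox.top) / jbox.height
            boxes_per_image.setdefault(img_idx, []).append(len(all_boxes))
            all_boxes.append([jbox.left, jbox.top, jbox.width, jbox.height])
            targets.append(t.ravel())
    boxes_arr = np.asarray(all_boxes)
    Y = np.asarray(targets)  # (N, 2L)
    mean_shape = Y.mean(axis=0).reshape(L, 2)

    current = np.tile(mean_shape.ravel(), (Y.shape[0], 1))
    stages: list[CascadeStage] = []
    for s in range(config.cascade_depth):
        points = rng.uniform(-0.15, 1.15, size=(config.n_candidate_points, 2))
        pairs = rng.integers(0, config.n_candidate_points, size=(config.n_features, 2))
        same = pairs[:, 0] == pairs[:, 1]
        pairs[same, 1] = (pairs[same, 1] + 1) % config.n_candidate_points
        groups = [
            (images[img_idx], boxes_arr[idx_list])
            for img_idx, idx_list in sorted(boxes_per_image.items())
        ]
        order = np.concatenate([boxes_per_image[i] for i in sorted(boxes_per_image)])
        X = np.empty((Y.shape[0], config.n_features))
        X[order] = _stage_features(groups, points, pairs)

        trees: list[DecisionTreeRegressor] = []
        for t in range(config.trees_per_stage):
            residual = Y - current
            tree = DecisionTreeRegressor(
                max_depth=config.tree_depth, random_state=int(config.seed + 1000 * s + t)
            )
            tree.fit(X, residual)
            current = current + config.nu * tree.predict(X)
            trees.append(tree)
        stages.append(CascadeStage(points=points, pairs=pairs, trees=trees))

    return ShapeModel(config=config, landmark_names=names, mean_shape=mean_shape, stages=stages)


def predict_landmarks(model: ShapeModel, image: np.ndarray, box: Box) -> LandmarkPrediction:
    """Run the cascade inside ``box`` and return landmarks in image coordinates."""
    L = len(model.landmark_names)
    boxes = np.array([[box.left, box.top, box.width, box.height]])
    current = model.mean_shape.ravel().copy()
    for stage in model.stages:
        inten = _sample_intensities(image, boxes, stage.points)
        x = (inten[:, stage.pairs[:, 0]] - inten[:, stage.pairs[:, 1]])
        for tree in stage.trees:
            current = current + model.config.nu * tree.predict(x)[0]
    shape = current.reshape(L, 2)
    landmarks = {
        name: Point2D(box.left + u * box.width, box.top + v * box.height)
        for name, (u, v) in zip(model.landmark_names, shape)
    }
    return LandmarkPrediction(landmarks=landmarks, source_box=box)
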