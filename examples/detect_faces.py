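"""Train the sliding-window face detector and score it on held-out images.

Prints precision and recall at the operating threshold and the
interpolated average precision at IoU 0.5 — the three detector metrics of
the evaluation protocol.
"""

from wildface import SyntheticDatasetConfig, generate_dataset, split_dataset, train_detector, detect_faces
from wildface.detection import DetectorConfig
from wildface.evaluation import evaluate_detections

m = generate_dataset(SyntheticDatasetConfig(n_identities=10, images_per_identity=8, seed=5))
train, test = split_dataset(m, 0.2, stratify_key="none", seed=0)
print(f"training on {len(train)} images, testing on {len(test)}")

detector = train_detector(train, config=DetectorConfig(hard_negative_rounds=1, seed=0))

gt = [img.annotations for img in test.images]
ranked = [detect_faces(detector, img.pixels, score_threshold=-1.0) for img in test.images]
# small training runs produce conservative scores, so operate at 0 here;
# the default threshold of 0.5 suits full-scale training
operating = [[d for d in dets if d.score >= 0.0] for dets in ranked]

op = evaluate_detections(gt, operating, 0.5)
ap = evaluate_detections(gt, ranked, 0.5).average_precision
print(f"precision {op.precision:.3f}  recall {op.recall:.3f}  AP@0.5 {ap:.3f}")
print("precision/recall are measured at the operating score threshold; AP "
      "integrates the interpolated precision-recall curve over the ranked "
      "detections, so it does not depend on the threshold.")
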