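# wildface

Individual identification of animals from face images. Many species of
conservation concern (bears are the motivating case) carry stable facial
markings and biometric structure that let trained observers tell
individuals apart from photographs; doing this manually is slow and hard
to standardize. `wildface` implements a complete, trainable pipeline for
the task — face detection, eye-landmark prediction, eye-aligned chip
extraction, metric-embedding verification, and closed-set identification —
together with the full evaluation methodology used to judge each stage,
and a synthetic face generator with exact ground truth so the whole system
can be trained and tested end to end without any real photographs.

The intended users are researchers building photo-ID pipelines for
camera-trap or zoo imagery, and anyone who needs a desk-scale, fully
inspectable reference implementation of this class of system.

## Pipeline

1. **Detection.** A sliding window over a gradient-orientation-histogram
   (HOG) feature pyramid, scored by a max-margin linear model
   (Dalal–Triggs lineage) trained with hard-negative mining, followed by
   greedy non-maximum suppression. A detection is correct when its
   intersection-over-union with a ground-truth box reaches 0.5.
2. **Landmarks.** A cascade of gradient-boosted regression trees places
   the two outer eye corners inside each detected box. Stage features are
   pixel-intensity differences at box-relative positions; trees are fit by
   greedy variance reduction with shrinkage ν.
3. **Chipping.** The exact two-point similarity transform maps the eye
   corners to canonical positions in a fixed 150×150 chip, cancelling
   in-plane rotation and scale.
4. **Embedding.** Each chip's HOG descriptor is projected by a learned
   linear map into R^D (D = 128). The projection minimizes a pairwise
   hinge loss around an operating distance threshold τ: matching pairs are
   penalized when ‖e_a − e_b‖ > τ − m, non-matching pairs when
   ‖e_a − e_b‖ < τ + m, with margin m.
5. **Identification.** A one-vs-rest linear SVM over embeddings assigns
   one of the known individuals (closed set).

## Evaluation methodology

* Detection: precision TP/(TP+FP), recall TP/(TP+FN), and interpolated
  average precision — the area under the precision–recall curve with the
  precision envelope taken as a running maximum, no credit beyond the
  achieved recall.
* Landmarks: per-face mean landmark error divided by the true
  inter-ocular distance, reported mean ± SD.
* Verification: balanced pair sets (equal matching and non-matching
  counts, unique, no self-pairs); accuracy = TPR × positive ratio + TNR ×
  negative ratio, F1 = 2·precision·recall/(precision+recall), plus full
  ROC curves.
* Two fivefold regimes: *folds across chips* (an individual's images may
  appear in every fold — the known-individual setting) and *folds by
  identity* (all of an individual's images confined to one fold — the
  novel-individual setting), reported mean ± SD across folds.
* End-to-end accounting: detected, missed and erroneous faces, and
  identification accuracy both over all input faces and over correctly
  detected faces, so cumulative upstream error is visible.

## Worked example

`examples/` contains one short script per capability. For instance,
verification (`python examples/verify_pairs.py`):

```
10 matching + 10 non-matching held-out pairs at tau=0.500
accuracy 0.950  TPR 1.000  TNR 0.900  F1 0.952  ROC AUC 1.000
```

Every matching pair of held-out chips fell below the operating threshold
(TPR 1.0), 9 of 10 non-matching pairs were rejected (TNR 0.9), giving a
balanced accuracy of 0.95; the AUC of 1.0 says the two distance
distributions are fully separable by some threshold. The other examples
print detection precision/recall/AP, normalized landmark error with the
chip eye-pinning residual, and the end-to-end accounting from input image
to individual ID.

The same stages are scriptable from a shell via the `wildface` console
tool (`generate`, `split`, `train-detector`, `train-shape`, `chip`,
`train-embed`, `train-svm`, `identify`, `evaluate`), reading and writing
imglab-style XML manifests:

```xml
<dataset><images>
  <image file='id_000_img_000.png' width='160' height='160'>
    <box top='30' left='25' width='82' height='88' species='ursid_a'>
      <label>id_000</label>
      <part name='leye' x='47.4900' y='69.9400'/>
      <part name='reye' x='84.4400' y='76.6500'/>
    </box>
  </image>
</images></dataset>
```

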