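"""Train the metric embedder and verify matching vs non-matching chip pairs.

Two chips 'match' when they show the same individual.  The embedder maps
each chip to a vector; a pair is predicted to match when the Euclidean
distance falls below the operating threshold tau.  Balanced accuracy
weighs the true-positive and true-negative rates equally, as the pair set
is built with equal class counts.
"""

import numpy as np

from wildface import SyntheticDatasetConfig, generate_dataset
from wildface.embedding import EmbedderConfig, featurize_chips, train_embedder_features
from wildface.evaluation import build_pair_set, roc_auc, roc_points, verification_metrics
from wildface.pipeline import golden_chips

m = generate_dataset(SyntheticDatasetConfig(n_identities=10, images_per_identity=10, seed=13))
chips = golden_chips(m)
labels = [c.identity for c in chips]
X = featurize_chips(chips)

# hold out two chips per individual for testing
rng = np.random.default_rng(0)
test_idx = sorted(
    int(i)
    for ident in sorted(set(labels))
    for i in rng.choice([j for j, l in enumerate(labels) if l == ident], 2, replace=False)
)
train_idx = sorted(set(range(len(labels))) - set(test_idx))

model = train_embedder_features(X[train_idx], [labels[i] for i in train_idx],
                                EmbedderConfig(seed=0, tune_tau=True))
emb = model.embed_features(X[test_idx])
te_labels = [labels[i] for i in test_idx]
pairs = build_pair_set(te_labels, 10, seed=1)
dists = [float(np.linalg.norm(emb[p.a] - emb[p.b])) for p in pairs]
out = verification_metrics(pairs, dists, model.tau)
auc = roc_auc(roc_points(pairs, dists))
print(f"{out.n_match} matching + {out.n_non} non-matching held-out pairs at tau={model.tau:.3f}")
print(f"accuracy {out.accuracy:.3f}  TPR {out.tpr:.3f}  TNR {out.tnr:.3f}  "
      f"F1 {out.f1:.3f}  ROC AUC {auc:.3f}")
print("TPR is the matched-pair hit rate, TNR the non-matched rejection "
      "rate; AUC summarizes separability over all possible thresholds.")
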