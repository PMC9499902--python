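"""Reference experiments: the full study on synthetic data, end to end.

``andean_study`` mirrors the complete evaluation protocol on one
generated dataset at the scale of a single-species subset (32
individuals, 7-40 images each, ~600 images total, split 80/20): it
trains every stage on the training split and reports detection,
landmark, verification, fold-regime and identification metrics on the
held-out split.  ``regime_gap`` repeats the two fivefold verification
regimes over several generated datasets and reports the mean accuracy of
each regime — the generalization contrast between verifying known
individuals (folds across chips) and novel individuals (folds by
identity).
"""

from __future__ import annotations

import warnings

import numpy as np

from . import evaluation
from .embedding import featurize_chips
from .manifest import split_dataset
from .pipeline import golden_chips, train_pipeline, evaluate_pipeline
from .synthetic import SyntheticDatasetConfig, generate_dataset

__all__ = ["andean_study", "regime_gap"]


def andean_study(seed: int = 0, config: SyntheticDatasetConfig | None = None) -> dict:
    """Generate, train, and evaluate the full pipeline; returns the report.

    The report contains the held-out pipeline evaluation (detection
    precision/recall/AP, normalized landmark error, verification at the
    operating threshold, closed-set identification, end-to-end counts)
    plus both fivefold verification regimes over all golden chips (214
    and 400 pairs per class, as in the protocol this mirrors).
    """
    cfg = config or SyntheticDatasetConfig(seed=seed)
    manifest = generate_dataset(cfg)
    train, test = split_dataset(manifest, 0.2, stratify_key="none", seed=seed)
    models = train_pipeline(train, seed=seed)
    report = evaluate_pipeline(models, test, seed=seed, n_pairs_per_class=230)

    chips = golden_chips(manifest, models.chip_spec)
    labels = [c.identity for c in chips]
    X = featurize_chips(chips, models.embedder.recipe)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        by_chip = evaluation.crossval_verification(X, labels, 5, "by_chip", seed=seed, n_pairs_per_class=214)
        by_id = evaluation.crossval_verification(X, labels, 5, "by_id", seed=seed, n_pairs_per_class=400)
    report["crossval_by_chip"] = by_chip.to_dict()
    report["crossval_by_id"] = by_id.to_dict()
    report["n_images"] = len(manifest)
    report["n_train"] = len(train)
    report["n_test"] = len(test)
    report["n_identities"] = len(manifest.identity_counts())
    return report


def regime_gap(
    n_seeds: int = 10,
    seed: int = 0,
    n_identities: int = 16,
    images_per_identity: int = 8,
    n_pairs_per_class: int = 50,
) -> dict:
    """Mean fivefold verification accuracy of both regimes over repeated
    datasets; the by-chip regime (known individuals) is expected to beat
    the by-identity regime (novel individuals) on average."""
    by_chip_accs: list[float] = []
    by_id_accs: list[float] = []
    for i in range(n_seeds):
        s = seed + 1000 * i
        cfg = SyntheticDatasetConfig(
            n_identities=n_identities, images_per_identity=images_per_identity, seed=s
        )
        chips = golden_chips(generate_dataset(cfg))
        labels = [c.identity for c in chips]
        X = featurize_chips(chips)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fc = evaluation.crossval_verification(X, labels, 5, "by_chip", seed=s, n_pairs_per_class=n_pairs_per_class)
            fi = evaluation.crossval_verification(X, labels, 5, "by_id", seed=s, n_pairs_per_class=n_pairs_per_class)
        by_chip_accs.append(fc.mean_accuracy)
        by_id_accs.append(fi.mean_accuracy)
    return {
        "n_seeds": n_seeds,
        "by_chip_accuracies": by_chip_accs,
        "by_id_accuracies": by_id_accs,
        "mean_by_chip": float(np.mean(by_chip_accs)),
        "mean_by_id": float(np.mean(by_id_accs)),
        "gap": float(np.mean(by_chip_accs) - np.mean(by_id_accs)),
    }
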