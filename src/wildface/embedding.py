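"""Metric embedding of face chips for same-individual verification.

Each chip is described by a fixed gradient-orientation-histogram
descriptor; a linear projection to D dimensions is then learned with a
pairwise hinge objective around an operating distance threshold tau:
matching pairs are penalized when their Euclidean distance exceeds
``tau - margin`` and non-matching pairs when it falls below
``tau + margin``.  The projection is initialized from a PCA of the
training descriptors (scaled so typical pair distances straddle tau) and
refined by full-batch gradient descent with early stopping.  Everything
is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .datatypes import ChipPair, Embedding, FaceChip
from .hog import HogParams, extract_hog

__all__ = [
    "EmbedRecipe",
    "EmbedderConfig",
    "EmbedderModel",
    "featurize_chip",
    "featurize_chips",
    "train_embedder",
    "train_embedder_features",
    "embed_chip",
    "pair_distance",
]


@dataclass(frozen=True)
class EmbedRecipe:
    """Descriptor layout for chips (HOG over the chip grid)."""

    cell_size: int = 15
    n_orientations: int = 9
    standardize_pixels: bool = True  # per-chip mean/variance normalization

    def hog_params(self) -> HogParams:
        return HogParams(cell_size=self.cell_size, n_orientations=self.n_orientations)


@dataclass(frozen=True)
class EmbedderConfig:
    D: int = 128
    margin: float = 0.1
    tau: float = 0.6
    tune_tau: bool = False  # re-fit tau on training pairs by accuracy maximization
    epochs: int = 300
    learning_rate: float = 0.05
    n_pairs_per_class: int = 1000
    pca_components: int = 256
    plateau_tol: float = 1e-6
    patience: int = 20
    seed: int = 0


@dataclass
class EmbedderModel:
    """Affine map descriptor -> R^D plus the operating threshold tau."""

    recipe: EmbedRecipe
    projection: np.ndarray  # (D, F)
    center: np.ndarray  # (F,)
    tau: float
    margin: float
    version: int = 1

    @property
    def D(self) -> int:
        return self.projection.shape[0]

    def embed_features(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.center) @ self.projection.T


def featurize_chip(chip: FaceChip | np.ndarray, recipe: EmbedRecipe | None = None) -> np.ndarray:
    """Deterministic chip descriptor; a constant chip maps to all zeros."""
    recipe = recipe or EmbedRecipe()
    pixels = chip.pixels if isinstance(chip, FaceChip) else chip
    if recipe.standardize_pixels:
        sd = pixels.std()
        if sd > 1e-12:
            pixels = (pixels - pixels.mean()) / sd
    return extract_hog(pixels, recipe.hog_params()).ravel()


def featurize_chips(chips: Sequence[FaceChip | np.ndarray], recipe: EmbedRecipe | None = None) -> np.ndarray:
    recipe = recipe or EmbedRecipe()
    return np.vstack([featurize_chip(c, recipe) for c in chips])


def _sample_training_pairs(
    labels: Sequence[str], n_per_class: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (matching, non-matching), unique, no self-pairs."""
    labels = np.asarray(labels)
    by_id: dict[str, np.ndarray] = {}
    for ident in np.unique(labels):
        by_id[ident] = np.nonzero(labels == ident)[0]
    match_all = [
        (int(idx[i]), int(idx[j]))
        for idx in by_id.values()
        for i in range(len(idx))
        for j in range(i + 1, len(idx))
    ]
    if not match_all:
        raise ValueError("no matching pairs possible: need >= 2 chips for some identity")
    if len(by_id) < 2:
        raise ValueError("need >= 2 identities to form non-matching pairs")
    if len(match_all) > n_per_class:
        sel = rng.choice(len(match_all), size=n_per_class, replace=False)
        match = [match_all[int(i)] for i in sorted(sel)]
    else:
        match = match_all
    n = len(labels)
    nonmatch: set[tuple[int, int]] = set()
    target = min(n_per_class, len(match) if len(match_all) <= n_per_class else n_per_class)
    attempts = 0
    while len(nonmatch) < target and attempts < 50 * target:
        i, j = int(rng.integers(0, n)), int(rng.integers(0, n))
        attempts += 1
        if i == j or labels[i] == labels[j]:
            continue
        nonmatch.add((min(i, j), max(i, j)))
    return np.asarray(match), np.asarray(sorted(nonmatch))


def train_embedder(
    chips: Sequence[FaceChip],
    config: EmbedderConfig | None = None,
    recipe: EmbedRecipe | None = None,
) -> EmbedderModel:
    """Learn the projection from labeled chips (identity on each chip)."""
    labels = [c.identity for c in chips]
    if any(l is None for l in labels):
        raise ValueError("all chips must carry an identity label for training")
    recipe = recipe or EmbedRecipe()
    X = featurize_chips(chips, recipe)
    return train_embedder_features(X, labels, config, recipe)


def train_embedder_features(
    X: np.ndarray,
    labels: Sequence[str],
    config: EmbedderConfig | None = None,
    recipe: EmbedRecipe | None = None,
) -> EmbedderModel:
    """Same as :func:`train_embedder` but on precomputed descriptors."""
    config = config or EmbedderConfig()
    recipe = recipe or EmbedRecipe()
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("need >= 2 identities to train the embedder")
    rng = np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=float)
    n, F = X.shape

    center = X.mean(axis=0)
    Xc = X - center
    k = min(config.pca_components, n - 1, F)
    # PCA basis via thin SVD (deterministic up to sign; fix signs)
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    Vt = Vt[:k]
    signs = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    Vt = Vt * signs[:, None]
    Z = Xc @ Vt.T  # (n, k)

    match, nonmatch = _sample_training_pairs(labels, config.n_pairs_per_class, rng)
    d_match = Z[match[:, 0]] - Z[match[:, 1]]
    d_non = Z[nonmatch[:, 0]] - Z[nonmatch[:, 1]]

    D = config.D
    W = np.zeros((D, k))
    W[: min(D, k), : min(D, k)] = np.eye(min(D, k))
    # scale so typical pair distances straddle tau
    dm = np.linalg.norm(d_match @ W.T, axis=1).mean()
    dn = np.linalg.norm(d_non @ W.T, axis=1).mean()
    mid = (dm + dn) / 2.0
    if mid > 1e-12:
        W *= config.tau / mid

    deltas = np.vstack([d_match, d_non])
    sign = np.concatenate([np.ones(len(d_match)), -np.ones(len(d_non))])
    lo = config.tau - config.margin
    hi = config.tau + config.margin
    bound = np.where(sign > 0, lo, hi)

    best_loss = np.inf
    stale = 0
    for _ in range(config.epochs):
        E = deltas @ W.T  # (P, D)
        d = np.linalg.norm(E, axis=1)
        viol = sign * (d - bound)  # >0 means hinge active
        active = viol > 0
        loss = float(np.sum(np.maximum(viol, 0))) / len(d)
        if loss < best_loss - config.plateau_tol:
            best_loss = loss
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
        if not np.any(active):
            break
        coeff = np.zeros_like(d)
        nz = active & (d > 1e-12)
        coeff[nz] = sign[nz] / d[nz]
        grad = (E * coeff[:, None]).T @ deltas / len(d)
        W = W - config.learning_rate * grad

    tau = config.tau
    if config.tune_tau:
        d_m = np.linalg.norm(d_match @ W.T, axis=1)
        d_n = np.linalg.norm(d_non @ W.T, axis=1)
        tau = _best_threshold(d_m, d_n)

    projection = W @ Vt  # (D, F)
    return EmbedderModel(recipe=recipe, projection=projection, center=center, tau=tau, margin=config.margin)


def _best_threshold(d_match: np.ndarray, d_non: np.ndarray) -> float:
    """Threshold maximizing balanced accuracy on the given distances."""
    cands = np.unique(np.concatenate([d_match, d_non]))
    cands = np.concatenate([cands, cands[:-1] + np.diff(cands) / 2.0]) if len(cands) > 1 else cands
    best_tau, best_acc = float(cands[0]), -1.0
    for t in np.sort(cands):
        acc = 0.5 * np.mean(d_match <= t) + 0.5 * np.mean(d_non > t)
        if acc > best_acc:
            best_acc, best_tau = acc, float(t)
    return best_tau


def embed_chip(model: EmbedderModel, chip: FaceChip) -> Embedding:
    """Project one chip; deterministic for a fixed model."""
    f = featurize_chip(chip, model.recipe)
    vec = model.embed_features(f)[0]
    return Embedding(vector=vec, identity=chip.identity, source_id=chip.source_id)


def pair_distance(a: Embedding | np.ndarray, b: Embedding | np.ndarray) -> float:
    """Euclidean distance between two embeddings of equal dimension."""
    va = a.vector if isinstance(a, Embedding) else np.asarray(a, dtype=float)
    vb = b.vector if isinstance(b, Embedding) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch: {va.shape} vs {vb.shape}")
    return float(np.linalg.norm(va - vb))
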