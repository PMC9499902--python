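"""Eye-aligned face chips: similarity transform to canonical eye positions.

Every detected face is mapped to a fixed-size square chip whose eye
corners land on canonical positions, cancelling in-plane rotation and
scale before embedding.  The two-point similarity transform has a closed
form (complex-plane solution); no reflection is ever introduced — left
versus right comes from the landmark names, not from geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .datatypes import FaceChip, Point2D

__all__ = ["ChipSpec", "SimilarityTransform", "fit_similarity_transform", "extract_chip"]


@dataclass(frozen=True)
class ChipSpec:
    """Chip geometry: square size and canonical (horizontal) eye positions."""

    chip_size: int = 150
    eye_x_fraction: float = 0.25  # leye at this fraction of width, reye mirrored
    eye_y_fraction: float = 0.40
    padding: float = 0.0

    @property
    def canonical_leye(self) -> Point2D:
        return Point2D(self.eye_x_fraction * self.chip_size, self.eye_y_fraction * self.chip_size)

    @property
    def canonical_reye(self) -> Point2D:
        return Point2D((1.0 - self.eye_x_fraction) * self.chip_size, self.eye_y_fraction * self.chip_size)


@dataclass(frozen=True)
class SimilarityTransform:
    """p -> scale * R(rotation) @ p + translation (x right, y down)."""

    rotation: float  # radians
    scale: float
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("similarity scale must be > 0")

    def apply(self, p: Point2D) -> Point2D:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        x = self.scale * (c * p.x - s * p.y) + self.translation[0]
        y = self.scale * (s * p.x + c * p.y) + self.translation[1]
        return Point2D(x, y)

    def inverse(self) -> "SimilarityTransform":
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        inv_scale = 1.0 / self.scale
        tx, ty = self.translation
        return SimilarityTransform(
            rotation=-self.rotation,
            scale=inv_scale,
            translation=(-inv_scale * (c * tx - s * ty), -inv_scale * (s * tx + c * ty)),
        )


def fit_similarity_transform(landmarks: dict[str, Point2D], spec: ChipSpec) -> SimilarityTransform:
    """Exact similarity mapping source eye corners onto the canonical ones.

    Solved in the complex plane: with source eyes ``s_l, s_r`` and
    canonical eyes ``c_l, c_r``, the map is ``z -> a z + b`` with
    ``a = (c_r - c_l) / (s_r - s_l)``.
    """
    try:
        sl, sr = landmarks["leye"], landmarks["reye"]
    except KeyError as exc:
        raise ValueError("both 'leye' and 'reye' landmarks are required") from exc
    s_l, s_r = complex(sl.x, sl.y), complex(sr.x, sr.y)
    if s_l == s_r:
        raise ValueError("degenerate geometry: coincident eye landmarks")
    cl, cr = spec.canonical_leye, spec.canonical_reye
    a = (complex(cr.x, cr.y) - complex(cl.x, cl.y)) / (s_r - s_l)
    b = complex(cl.x, cl.y) - a * s_l
    return SimilarityTransform(rotation=math.atan2(a.imag, a.real), scale=abs(a), translation=(b.real, b.imag))


def extract_chip(
    image: np.ndarray,
    landmarks: dict[str, Point2D],
    spec: ChipSpec | None = None,
    identity: Optional[str] = None,
    source_id: str = "",
) -> FaceChip:
    """Warp the eye-aligned chip out of the source image.

    Sampling is bilinear through the inverse map; pixels falling outside
    the source are edge-replicated.  The chip is exactly
    ``spec.chip_size`` square.
    """
    spec = spec or ChipSpec()
    tform = fit_similarity_transform(landmarks, spec)
    inv = tform.inverse()
    n = spec.chip_size
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    c, s = math.cos(inv.rotation), math.sin(inv.rotation)
    src_x = inv.scale * (c * xs - s * ys) + inv.translation[0]
    src_y = inv.scale * (s * xs + c * ys) + inv.translation[1]
    pixels = map_coordinates(image, [src_y, src_x], order=1, mode="nearest")
    return FaceChip(pixels=pixels, source_id=source_id, transform=tform, identity=identity)
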