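"""Core data carriers shared across the pipeline.

Coordinate conventions: pixel coordinates are 0-based, x grows to the
right and y grows downward.  Boxes are stored as (left, top, width,
height) with the left/top edge included; landmark coordinates are
continuous (sub-pixel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Point2D",
    "Box",
    "FaceAnnotation",
    "AnnotatedImage",
    "DatasetManifest",
    "Detection",
    "FaceChip",
    "Embedding",
    "IdentityPrediction",
    "ChipPair",
]


@dataclass(frozen=True)
class Point2D:
    """A continuous 2-D pixel position."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"Point2D coordinates must be finite, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Box:
    """Axis-aligned face bounding box, (left, top, width, height)."""

    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"Box must have positive dimensions, got width={self.width} height={self.height}"
            )

    @property
    def right(self) -> float:
        return self.left + self.width

    @property
    def bottom(self) -> float:
        return self.top + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> Point2D:
        return Point2D(self.left + self.width / 2.0, self.top + self.height / 2.0)

    def intersects(self, other: "Box") -> bool:
        return (
            self.left < other.right
            and other.left < self.right
            and self.top < other.bottom
            and other.top < self.bottom
        )

    def translated(self, dx: float, dy: float) -> "Box":
        return Box(self.left + dx, self.top + dy, self.width, self.height)

    def scaled(self, s: float) -> "Box":
        return Box(self.left * s, self.top * s, self.width * s, self.height * s)


@dataclass
class FaceAnnotation:
    """Ground-truth face: box, named landmarks, optional identity metadata.

    Landmark names are free-form; the pipeline's default set is the two
    outer eye corners, ``"leye"`` and ``"reye"``.
    """

    box: Box
    landmarks: dict[str, Point2D] = field(default_factory=dict)
    identity: Optional[str] = None
    species: Optional[str] = None
    capture_date: Optional[str] = None  # ISO "YYYY-MM-DD" or None
    age_years: Optional[float] = None
    extra: dict[str, str] = field(default_factory=dict)

    def interocular_distance(self) -> Optional[float]:
        if "leye" in self.landmarks and "reye" in self.landmarks:
            return self.landmarks["leye"].distance_to(self.landmarks["reye"])
        return None

    def validate(self, image_width: Optional[int] = None, image_height: Optional[int] = None) -> None:
        iod = self.interocular_distance()
        if iod is not None and iod <= 0:
            raise ValueError("inter-ocular distance must be > 0 when both eyes are annotated")
        if image_width is not None and image_height is not None:
            for name, pt in self.landmarks.items():
                if not (0 <= pt.x <= image_width and 0 <= pt.y <= image_height):
                    raise ValueError(
                        f"landmark {name!r} at ({pt.x}, {pt.y}) lies outside the "
                        f"{image_width}x{image_height} image"
                    )


@dataclass
class AnnotatedImage:
    """A raster with its ground-truth face annotations.

    ``pixels`` is lazy: manifests carry only the path (``source_id``) and
    annotations; call :func:`wildface.manifest.load_image` to fill the
    luminance raster (float in [0, 1]).
    """

    source_id: str
    width: Optional[int] = None
    height: Optional[int] = None
    pixels: Optional[np.ndarray] = None
    annotations: list[FaceAnnotation] = field(default_factory=list)

    def validate(self) -> None:
        if self.pixels is not None:
            h, w = self.pixels.shape
            if self.width is not None and (w != self.width or h != self.height):
                raise ValueError(
                    f"{self.source_id}: raster is {w}x{h} but manifest declares "
                    f"{self.width}x{self.height}"
                )
        if self.width is not None and self.height is not None:
            frame = Box(0, 0, self.width, self.height)
            for ann in self.annotations:
                if not ann.box.intersects(frame):
                    raise ValueError(f"{self.source_id}: annotation box does not intersect the image")


@dataclass
class DatasetManifest:
    """Ordered collection of annotated images plus free-text provenance."""

    images: list[AnnotatedImage] = field(default_factory=list)
    name: str = ""
    comment: str = ""
    base_dir: str = ""

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)

    def validate(self) -> None:
        ids = [im.source_id for im in self.images]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate source_ids in manifest: {dupes}")
        for im in self.images:
            im.validate()

    def annotations(self):
        """Yield (image, annotation) pairs in manifest order."""
        for im in self.images:
            for ann in im.annotations:
                yield im, ann

    def identity_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, ann in self.annotations():
            if ann.identity is not None:
                counts[ann.identity] = counts.get(ann.identity, 0) + 1
        return counts


@dataclass
class Detection:
    """Predicted face box with score; landmarks filled by the shape stage."""

    box: Box
    score: float
    landmarks: Optional[dict[str, Point2D]] = None


@dataclass
class FaceChip:
    """Fixed-size eye-aligned crop with its provenance."""

    pixels: np.ndarray
    source_id: str = ""
    transform: Optional["object"] = None  # SimilarityTransform; avoids import cycle
    identity: Optional[str] = None


@dataclass
class Embedding:
    """Fixed-dimension vector representation of one chip."""

    vector: np.ndarray
    identity: Optional[str] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding vector must be finite")


@dataclass
class IdentityPrediction:
    """Closed-set identity decision with its per-class margins."""

    label: str
    margin: float
    scores: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ChipPair:
    """An unordered test pair of chips with its match label.

    ``a`` and ``b`` are indices into a chip list; ``is_match`` is True when
    both chips show the same individual.
    """

    a: int
    b: int
    is_match: bool

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-pairs are not allowed")

    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)
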