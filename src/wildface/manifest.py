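"""Dataset manifest I/O in an imglab-style XML dialect, plus splits and filters.

The on-disk dialect mirrors the XML emitted by dlib's ``imglab`` annotation
tool::

    <dataset>
      <name>...</name>
      <comment>...</comment>
      <images>
        <image file='relative/or/absolute.png' width='160' height='160'>
          <box top='20' left='30' width='50' height='48' species='...' date='2020-05-01'>
            <label>id_007</label>
            <part name='leye' x='45.1250' y='62.0000'/>
            <part name='reye' x='70.2500' y='62.0000'/>
          </box>
        </image>
      </images>
    </dataset>

Box geometry is written exactly (integers stay integers); part coordinates
are written to 4 decimal places, which is the declared round-trip precision
for landmarks.  Unknown box attributes are retained verbatim so external
tools can annotate freely.
"""

from __future__ import annotations

import math
import os
import warnings
from typing import Optional

import numpy as np
from lxml import etree
from PIL import Image

from .datatypes import AnnotatedImage, Box, DatasetManifest, FaceAnnotation, Point2D

__all__ = [
    "read_manifest",
    "write_manifest",
    "load_image",
    "split_dataset",
    "filter_subset",
    "ManifestError",
]

PART_PRECISION = 4  # decimal places preserved for landmark coordinates

_KNOWN_BOX_ATTRS = {"top", "left", "width", "height", "species", "date", "age"}
SUPPORTED_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


class ManifestError(ValueError):
    """Raised for malformed or invalid manifest files."""


def _fmt_num(v: float) -> str:
    """Integers render bare; other values keep full precision."""
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def _fmt_part(v: float) -> str:
    return f"{float(v):.{PART_PRECISION}f}"


def read_manifest(path: str) -> DatasetManifest:
    """Parse an imglab-style XML file into a :class:`DatasetManifest`.

    Raises :class:`ManifestError` naming the offending line for malformed
    XML and the offending image for invalid box geometry.
    """
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise ManifestError(f"malformed XML in {path}: line {exc.lineno}: {exc.msg}") from exc
    root = tree.getroot()
    if root.tag != "dataset":
        raise ManifestError(f"{path}: root element is <{root.tag}>, expected <dataset>")

    manifest = DatasetManifest(base_dir=os.path.dirname(os.path.abspath(path)))
    name_el = root.find("name")
    comment_el = root.find("comment")
    manifest.name = name_el.text or "" if name_el is not None else ""
    manifest.comment = comment_el.text or "" if comment_el is not None else ""

    images_el = root.find("images")
    if images_el is None:
        return manifest

    for image_el in images_el.findall("image"):
        file_attr = image_el.get("file")
        if file_attr is None:
            raise ManifestError(f"{path}: <image> element without a file attribute")
        img = AnnotatedImage(
            source_id=file_attr,
            width=int(image_el.get("width")) if image_el.get("width") else None,
            height=int(image_el.get("height")) if image_el.get("height") else None,
        )
        for box_el in image_el.findall("box"):
            try:
                geom = {k: float(box_el.get(k)) for k in ("left", "top", "width", "height")}
            except (TypeError, ValueError) as exc:
                raise ManifestError(f"{path}: image {file_attr!r}: box missing numeric geometry") from exc
            if geom["width"] <= 0 or geom["height"] <= 0:
                raise ManifestError(
                    f"{path}: image {file_attr!r}: box has non-positive dimensions "
                    f"(width={geom['width']}, height={geom['height']})"
                )
            ann = FaceAnnotation(box=Box(**geom))
            ann.species = box_el.get("species")
            ann.capture_date = box_el.get("date")
            age = box_el.get("age")
            ann.age_years = float(age) if age is not None else None
            ann.extra = {k: v for k, v in box_el.attrib.items() if k not in _KNOWN_BOX_ATTRS}
            label_el = box_el.find("label")
            if label_el is not None and label_el.text:
                ann.identity = label_el.text
            for part_el in box_el.findall("part"):
                pname = part_el.get("name")
                if pname is None:
                    raise ManifestError(f"{path}: image {file_attr!r}: <part> without a name")
                ann.landmarks[pname] = Point2D(float(part_el.get("x")), float(part_el.get("y")))
            img.annotations.append(ann)
        manifest.images.append(img)
    manifest.validate()
    return manifest


def write_manifest(manifest: DatasetManifest, path: str) -> None:
    """Serialize a manifest to canonical imglab-style XML.

    Element and attribute order is deterministic, so writing the result of
    :func:`read_manifest` reproduces the file byte-for-byte.
    """
    out_dir = os.path.dirname(os.path.abspath(path))
    root = etree.Element("dataset")
    etree.SubElement(root, "name").text = manifest.name or None
    etree.SubElement(root, "comment").text = manifest.comment or None
    images_el = etree.SubElement(root, "images")
    for img in manifest.images:
        image_el = etree.SubElement(images_el, "image")
        sid = img.source_id
        if not os.path.isabs(sid) and manifest.base_dir:
            # keep file references valid relative to the new manifest location
            sid = os.path.relpath(os.path.join(manifest.base_dir, sid), out_dir)
        image_el.set("file", sid)
        if img.width is not None:
            image_el.set("width", str(img.width))
        if img.height is not None:
            image_el.set("height", str(img.height))
        for ann in img.annotations:
            box_el = etree.SubElement(image_el, "box")
            box_el.set("top", _fmt_num(ann.box.top))
            box_el.set("left", _fmt_num(ann.box.left))
            box_el.set("width", _fmt_num(ann.box.width))
            box_el.set("height", _fmt_num(ann.box.height))
            if ann.species is not None:
                box_el.set("species", ann.species)
            if ann.capture_date is not None:
                box_el.set("date", ann.capture_date)
            if ann.age_years is not None:
                box_el.set("age", _fmt_num(ann.age_years))
            for k in sorted(ann.extra):
                box_el.set(k, ann.extra[k])
            if ann.identity is not None:
                etree.SubElement(box_el, "label").text = ann.identity
            for pname in sorted(ann.landmarks):
                part_el = etree.SubElement(box_el, "part")
                part_el.set("name", pname)
                part_el.set("x", _fmt_part(ann.landmarks[pname].x))
                part_el.set("y", _fmt_part(ann.landmarks[pname].y))
    etree.indent(root, space="  ")
    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=False)
    with open(path, "wb") as fh:
        fh.write(data)
        fh.write(b"\n")


def load_image(source_id: str, base_dir: str = "") -> np.ndarray:
    """Load a JPEG/PNG/TIFF image as a luminance raster in [0, 1].

    TIFF inputs are converted transparently on load.  Unsupported
    extensions raise a format error naming the extension.
    """
    ext = os.path.splitext(source_id)[1].lower()
    if ext not in SUPPORTED_IMAGE_EXTENSIONS:
        raise ValueError(f"unsupported image format {ext!r} (supported: JPEG, PNG, TIFF)")
    path = source_id if os.path.isabs(source_id) or not base_dir else os.path.join(base_dir, source_id)
    with Image.open(path) as im:
        gray = im.convert("L")
        arr = np.asarray(gray, dtype=np.float64) / 255.0
    return arr


def _image_stratum(img: AnnotatedImage, key: str) -> str:
    if key == "none":
        return ""
    for ann in img.annotations:
        v = getattr(ann, key, None)
        if v is not None:
            return str(v)
    return ""


def _independence_groups(images: list[AnnotatedImage]) -> list[list[int]]:
    """Group image indices by (identity, capture date); missing dates are singletons."""
    groups: dict[tuple[str, str], list[int]] = {}
    singles: list[list[int]] = []
    for i, img in enumerate(images):
        ann = img.annotations[0] if img.annotations else None
        ident = ann.identity if ann is not None else None
        date = ann.capture_date if ann is not None else None
        if ident is None or date is None:
            singles.append([i])
        else:
            groups.setdefault((ident, date), []).append(i)
    return list(groups.values()) + singles


def split_dataset(
    manifest: DatasetManifest,
    test_fraction: float,
    stratify_key: str = "none",
    seed: int = 0,
    group_by_day: bool = False,
) -> tuple[DatasetManifest, DatasetManifest]:
    """Random train/test split with per-stratum exact floor counts.

    The overall test count is exactly ``floor(test_fraction * N)``;
    within each stratum of size ``n`` the test partition receives
    ``floor(test_fraction * n)`` images, with the leftover seats assigned
    by largest fractional remainder (ties to the lexicographically first
    stratum), all chosen uniformly at random.  With ``group_by_day`` set,
    images of one individual taken on the same calendar day stay on one
    side of the split (the test count then becomes approximate: groups
    are drawn until the stratum target is reached or exceeded).
    """
    if not (0 < test_fraction < 1):
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[int]] = {}
    for i, img in enumerate(manifest.images):
        strata.setdefault(_image_stratum(img, stratify_key), []).append(i)

    names = sorted(strata)
    exact = {s: test_fraction * len(strata[s]) for s in names}
    targets = {s: math.floor(exact[s]) for s in names}
    leftover = math.floor(test_fraction * len(manifest.images)) - sum(targets.values())
    for s in sorted(names, key=lambda s: (-(exact[s] - targets[s]), s))[: max(0, leftover)]:
        targets[s] += 1

    train_idx: list[int] = []
    test_idx: list[int] = []
    for stratum in names:
        members = strata[stratum]
        n = len(members)
        if n == 0:  # pragma: no cover - defensive
            warnings.warn(f"stratum {stratum!r} is empty; skipped")
            continue
        n_test = targets[stratum]
        if group_by_day:
            groups = _independence_groups([manifest.images[i] for i in members])
            order = rng.permutation(len(groups))
            picked: list[int] = []
            for gi in order:
                if len(picked) >= n_test:
                    break
                picked.extend(members[j] for j in groups[gi])
            picked_set = set(picked)
            test_idx.extend(sorted(picked_set))
            train_idx.extend(i for i in members if i not in picked_set)
        else:
            chosen = rng.choice(n, size=n_test, replace=False)
            chosen_set = {members[int(c)] for c in chosen}
            test_idx.extend(sorted(chosen_set))
            train_idx.extend(i for i in members if i not in chosen_set)

    if not test_idx:
        raise ValueError("test_fraction yields an empty test set")
    train_idx.sort()
    test_idx.sort()
    mk = lambda idx: DatasetManifest(  # noqa: E731
        images=[manifest.images[i] for i in idx],
        name=manifest.name,
        comment=manifest.comment,
        base_dir=manifest.base_dir,
    )
    return mk(train_idx), mk(test_idx)


def filter_subset(
    manifest: DatasetManifest,
    min_images_per_identity: int = 1,
    min_age_years: Optional[float] = None,
    report: Optional[dict] = None,
) -> DatasetManifest:
    """Keep only annotations of identities with enough images.

    The optional age threshold is applied first (annotations without age
    metadata are excluded and counted in ``report["missing_age"]``); then
    identities with fewer than ``min_images_per_identity`` surviving
    annotations are dropped.  Images left with no annotations are removed.
    The operation is idempotent.
    """
    if report is None:
        report = {}
    report.setdefault("missing_age", 0)

    def age_ok(ann: FaceAnnotation) -> bool:
        if min_age_years is None:
            return True
        if ann.age_years is None:
            report["missing_age"] += 1
            return False
        return ann.age_years >= min_age_years

    kept: list[tuple[int, FaceAnnotation]] = []
    counts: dict[str, int] = {}
    for i, img in enumerate(manifest.images):
        for ann in img.annotations:
            if ann.identity is not None and age_ok(ann):
                kept.append((i, ann))
                counts[ann.identity] = counts.get(ann.identity, 0) + 1

    surviving = {ident for ident, c in counts.items() if c >= min_images_per_identity}
    out = DatasetManifest(name=manifest.name, comment=manifest.comment, base_dir=manifest.base_dir)
    for i, img in enumerate(manifest.images):
        anns = [ann for j, ann in kept if j == i and ann.identity in surviving]
        if anns:
            out.images.append(
                AnnotatedImage(
                    source_id=img.source_id,
                    width=img.width,
                    height=img.height,
                    pixels=img.pixels,
                    annotations=anns,
                )
            )
    return out
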