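"""Manifest round-trips, image loading, splits and identity filters."""

from __future__ import annotations

import numpy as np
import pytest
from PIL import Image

from wildface.datatypes import AnnotatedImage, Box, DatasetManifest, FaceAnnotation, Point2D
from wildface.manifest import (
    ManifestError,
    filter_subset,
    load_image,
    read_manifest,
    split_dataset,
    write_manifest,
)


def make_manifest(counts: dict[str, int], size: int = 100) -> DatasetManifest:
    m = DatasetManifest(name="t")
    for sp, n in counts.items():
        for i in range(n):
            ann = FaceAnnotation(box=Box(5, 5, 20, 20), species=sp, identity=f"{sp}_{i % 3}")
            m.images.append(
                AnnotatedImage(source_id=f"{sp}_{i}.png", width=size, height=size, annotations=[ann])
            )
    return m


def random_manifest(rng: np.random.Generator, n_images: int) -> DatasetManifest:
    m = DatasetManifest(name="rand", comment="c")
    for i in range(n_images):
        w, h = int(rng.integers(50, 400)), int(rng.integers(50, 400))
        img = AnnotatedImage(source_id=f"im_{i:03d}.png", width=w, height=h)
        for _ in range(int(rng.integers(0, 3))):
            bw, bh = rng.uniform(5, w / 2), rng.uniform(5, h / 2)
            left, top = rng.uniform(0, w - bw), rng.uniform(0, h - bh)
            ann = FaceAnnotation(box=Box(round(left, 4), round(top, 4), round(bw, 4), round(bh, 4)))
            if rng.random() < 0.8:
                cx, cy = left + bw / 2, top + bh / 2
                ann.landmarks = {
                    "leye": Point2D(round(cx - bw / 4, 4), round(cy, 4)),
                    "reye": Point2D(round(cx + bw / 4, 4), round(cy, 4)),
                }
            if rng.random() < 0.7:
                ann.identity = f"id_{int(rng.integers(0, 5))}"
            if rng.random() < 0.5:
                ann.species = f"sp{int(rng.integers(0, 3))}"
            if rng.random() < 0.3:
                ann.capture_date = "2020-01-0" + str(int(rng.integers(1, 9)))
            img.annotations.append(ann)
        m.images.append(img)
    return m


class TestRoundTrip:
    def test_empty_manifest(self, tmp_path):
        p = str(tmp_path / "empty.xml")
        write_manifest(DatasetManifest(), p)
        m = read_manifest(p)
        assert len(m) == 0
        assert b"<image " not in open(p, "rb").read()

    def test_single_image_preserves_values(self, tmp_path):
        m = DatasetManifest()
        ann = FaceAnnotation(
            box=Box(10, 20, 30, 30),
            landmarks={"leye": Point2D(15.5, 30.25), "reye": Point2D(32.0, 30.25)},
            identity="I843",
        )
        m.images.append(AnnotatedImage(source_id="a.png", width=64, height=64, annotations=[ann]))
        p = str(tmp_path / "one.xml")
        write_manifest(m, p)
        m2 = read_manifest(p)
        a2 = m2.images[0].annotations[0]
        assert a2.box == Box(10, 20, 30, 30)
        assert a2.landmarks["leye"] == Point2D(15.5, 30.25)
        assert a2.identity == "I843"

    @pytest.mark.parametrize("seed", range(4))
    def test_write_read_write_byte_identical(self, tmp_path, seed):
        """write(read(f)) byte-compares equal for randomized 25-image manifests."""
        rng = np.random.default_rng(seed)
        m = random_manifest(rng, 25)
        p1, p2 = str(tmp_path / "a.xml"), str(tmp_path / "b.xml")
        write_manifest(m, p1)
        write_manifest(read_manifest(p1), p2)
        assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_many_random_manifests_round_trip(self, tmp_path):
        rng = np.random.default_rng(99)
        for i in range(100):
            m = random_manifest(rng, int(rng.integers(0, 8)))
            p = str(tmp_path / f"m{i}.xml")
            write_manifest(m, p)
            m2 = read_manifest(p)
            assert len(m2) == len(m)
            for im1, im2 in zip(m.images, m2.images):
                assert im1.source_id == im2.source_id
                assert len(im1.annotations) == len(im2.annotations)
                for a1, a2 in zip(im1.annotations, im2.annotations):
                    assert a1.box == a2.box
                    assert a1.identity == a2.identity
                    assert set(a1.landmarks) == set(a2.landmarks)
                    for k in a1.landmarks:
                        assert a1.landmarks[k].distance_to(a2.landmarks[k]) < 1e-4

    def test_malformed_xml_names_line(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<dataset>\n<images>\n<image file='x'>\n</dataset>")
        with pytest.raises(ManifestError, match="line"):
            read_manifest(str(p))

    def test_negative_box_dimensions_name_image(self, tmp_path):
        p = tmp_path / "neg.xml"
        p.write_text(
            "<dataset><images><image file='z.png'>"
            "<box top='1' left='1' width='-5' height='4'/></image></images></dataset>"
        )
        with pytest.raises(ManifestError, match="z.png"):
            read_manifest(str(p))

    def test_unknown_attributes_retained(self, tmp_path):
        p = tmp_path / "extra.xml"
        p.write_text(
            "<dataset><images><image file='z.png'>"
            "<box top='1' left='1' width='5' height='4' pose='frontal'/></image></images></dataset>"
        )
        m = read_manifest(str(p))
        assert m.images[0].annotations[0].extra == {"pose": "frontal"}
        out = str(p) + ".out"
        write_manifest(m, out)
        assert read_manifest(out).images[0].annotations[0].extra == {"pose": "frontal"}


class TestLoadImage:
    def test_constant_png_maps_to_unit(self, tmp_path):
        p = str(tmp_path / "white.png")
        Image.fromarray(np.full((8, 8), 255, np.uint8)).save(p)
        arr = load_image(p)
        assert np.allclose(arr, 1.0)

    def test_jpeg_shape(self, tmp_path):
        p = str(tmp_path / "x.jpg")
        Image.fromarray(np.zeros((10, 10), np.uint8)).save(p)
        assert load_image(p).shape == (10, 10)

    def test_png_vs_tiff_agree(self, tmp_path):
        rng = np.random.default_rng(0)
        scene = (rng.uniform(0, 1, (32, 32)) * 255).astype(np.uint8)
        p1, p2 = str(tmp_path / "s.png"), str(tmp_path / "s.tiff")
        Image.fromarray(scene).save(p1)
        Image.fromarray(scene).save(p2)
        assert np.mean(np.abs(load_image(p1) - load_image(p2))) <= 0.02

    def test_unsupported_extension(self, tmp_path):
        p = tmp_path / "x.bmp"
        p.write_bytes(b"")
        with pytest.raises(ValueError, match=".bmp"):
            load_image(str(p))


class TestSplit:
    def test_single_stratum_609(self):
        m = make_manifest({"andean": 609})
        tr, te = split_dataset(m, 0.2, "species", seed=0)
        assert (len(tr), len(te)) == (488, 121)

    def test_species_strata_2192(self):
        counts = {
            "amblack": 84,
            "andean": 609,
            "asblack": 54,
            "brown": 588,
            "panda": 185,
            "polar": 481,
            "sloth": 92,
            "sun": 99,
        }
        m = make_manifest(counts)
        tr, te = split_dataset(m, 0.2, "species", seed=0)
        assert (len(tr), len(te)) == (1754, 438)

    def test_tiny_floor(self):
        m = make_manifest({"a": 5})
        tr, te = split_dataset(m, 0.2, "none", seed=0)
        assert (len(tr), len(te)) == (4, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_disjoint_exhaustive_and_stratum_counts(self, seed):
        rng = np.random.default_rng(seed)
        counts = {f"s{i}": int(rng.integers(3, 40)) for i in range(4)}
        m = make_manifest(counts)
        frac = float(rng.uniform(0.1, 0.5))
        tr, te = split_dataset(m, frac, "species", seed=seed)
        ids_tr = {im.source_id for im in tr.images}
        ids_te = {im.source_id for im in te.images}
        assert ids_tr.isdisjoint(ids_te)
        assert len(ids_tr | ids_te) == len(m)
        assert len(te) == int(np.floor(frac * len(m)))
        for sp, n in counts.items():
            n_te = sum(1 for im in te.images if im.annotations[0].species == sp)
            assert n_te in (int(np.floor(frac * n)), int(np.floor(frac * n)) + 1)

    def test_group_by_day_keeps_same_day_together(self):
        m = DatasetManifest()
        for i in range(30):
            ann = FaceAnnotation(
                box=Box(0, 0, 5, 5), identity=f"id_{i % 5}", capture_date=f"2020-01-{(i % 6) + 1:02d}"
            )
            m.images.append(AnnotatedImage(source_id=f"g{i}.png", width=10, height=10, annotations=[ann]))
        tr, te = split_dataset(m, 0.3, "none", seed=1, group_by_day=True)
        te_groups = {(im.annotations[0].identity, im.annotations[0].capture_date) for im in te.images}
        for im in tr.images:
            key = (im.annotations[0].identity, im.annotations[0].capture_date)
            assert key not in te_groups

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(make_manifest({"a": 10}), 0.0, "none", 0)


class TestFilterSubset:
    @staticmethod
    def by_identity(counts: dict[str, int]) -> DatasetManifest:
        m = DatasetManifest()
        for ident, n in counts.items():
            for i in range(n):
                ann = FaceAnnotation(box=Box(0, 0, 5, 5), identity=ident)
                m.images.append(
                    AnnotatedImage(source_id=f"{ident}_{i}.png", width=10, height=10, annotations=[ann])
                )
        return m

    def test_threshold_boundary_keeps_seven(self):
        m = self.by_identity({"A": 7, "B": 6, "C": 10})
        out = filter_subset(m, min_images_per_identity=7)
        assert set(out.identity_counts()) == {"A", "C"}
        assert len(out) == 17

    def test_min_one_is_identity(self):
        m = self.by_identity({"A": 3, "B": 1})
        out = filter_subset(m, 1)
        assert len(out) == len(m)

    def test_idempotent(self):
        m = self.by_identity({"A": 9, "B": 2, "C": 5})
        once = filter_subset(m, 5)
        twice = filter_subset(once, 5)
        assert [im.source_id for im in once.images] == [im.source_id for im in twice.images]

    @pytest.mark.parametrize("seed", range(5))
    def test_surviving_counts_vs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        counts = {f"i{j}": int(rng.integers(1, 12)) for j in range(8)}
        k = int(rng.integers(2, 8))
        out = filter_subset(self.by_identity(counts), k)
        recount: dict[str, int] = {}
        for im in out.images:
            for ann in im.annotations:
                recount[ann.identity] = recount.get(ann.identity, 0) + 1
        assert recount == {i: n for i, n in counts.items() if n >= k}
        assert all(v >= k for v in recount.values())

    def test_age_filter_reports_missing(self):
        m = self.by_identity({"A": 4})
        m.images[0].annotations[0].age_years = 1.0
        m.images[1].annotations[0].age_years = 5.0
        report: dict = {}
        out = filter_subset(m, 1, min_age_years=2.0, report=report)
        assert report["missing_age"] == 2
        assert len(out) == 1
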