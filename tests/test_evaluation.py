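"""Metric arithmetic, oracles for AP/matching/ROC, folds, and accounting."""

from __future__ import annotations

import numpy as np
import pytest

from wildface import evaluation as ev
from wildface.datatypes import Box, ChipPair, Detection, FaceAnnotation, Point2D


def random_scene(rng, n_gt_max=4, n_det_max=6):
    gts = [
        FaceAnnotation(box=Box(rng.uniform(0, 60), rng.uniform(0, 60), rng.uniform(10, 30), rng.uniform(10, 30)))
        for _ in range(int(rng.integers(0, n_gt_max + 1)))
    ]
    dets = []
    for _ in range(int(rng.integers(0, n_det_max + 1))):
        if gts and rng.random() < 0.6:
            g = gts[int(rng.integers(0, len(gts)))].box
            b = Box(
                g.left + rng.normal(0, 4), g.top + rng.normal(0, 4), g.width * rng.uniform(0.7, 1.3), g.height * rng.uniform(0.7, 1.3)
            )
        else:
            b = Box(rng.uniform(0, 70), rng.uniform(0, 70), rng.uniform(8, 25), rng.uniform(8, 25))
        dets.append(Detection(box=b, score=float(rng.normal())))
    return gts, dets


def reference_match(gts, dets, thr):
    """Independent counting reference for the greedy assignment."""
    from wildface.detection import iou

    free = set(range(len(gts)))
    tp = 0
    for d in sorted(dets, key=lambda d: -d.score):
        cands = sorted(
            ((iou(d.box, gts[j].box), -j) for j in free),
            reverse=True,
        )
        if cands and cands[0][0] >= thr:
            free.discard(-cands[0][1])
            tp += 1
    return tp, len(dets) - tp, len(gts) - tp


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,expect",
        [(104, 121, 86.0), (108, 121, 89.3), (104, 120, 86.7), (10, 11, 90.9), (609, 500 * 609 // 500, 100.0)],
    )
    def test_ratio_to_one_decimal_half_up(self, num, den, expect):
        assert ev.percent(num / den) == expect

    def test_half_up_at_boundary(self):
        assert ev.percent(0.9085) == 90.9
        assert ev.percent(0.90849) == 90.8


class TestMatchDetections:
    def test_perfect_single_match(self):
        gt = [FaceAnnotation(box=Box(0, 0, 10, 10))]
        det = [Detection(box=Box(0, 0, 10, 10), score=1.0)]
        a = ev.match_detections(gt, det)
        assert (a.tp, a.fp, a.fn) == (1, 0, 0)

    def test_double_detection_counts_one_fp(self):
        gt = [FaceAnnotation(box=Box(0, 0, 10, 10))]
        det = [Detection(box=Box(0, 0, 10, 10), score=1.0), Detection(box=Box(1, 1, 10, 10), score=0.9)]
        a = ev.match_detections(gt, det)
        assert (a.tp, a.fp, a.fn) == (1, 1, 0)

    @pytest.mark.parametrize("seed", range(30))
    def test_counts_match_reference_on_random_scenes(self, seed):
        rng = np.random.default_rng(seed)
        gts, dets = random_scene(rng)
        a = ev.match_detections(gts, dets, 0.5)
        assert (a.tp, a.fp, a.fn) == reference_match(gts, dets, 0.5)


class TestDetectionMetrics:
    def test_eleven_faces_ten_found(self):
        gt = [FaceAnnotation(box=Box(20 * i, 0, 10, 10)) for i in range(11)]
        det = [Detection(box=Box(20 * i, 0, 10, 10), score=1.0 - 0.01 * i) for i in range(10)]
        a = ev.match_detections(gt, det)
        p, r = ev.detection_metrics(a)
        assert p == pytest.approx(1.000)
        assert round(r, 3) == 0.909

    def test_nothing_detected(self):
        gt = [FaceAnnotation(box=Box(0, 0, 5, 5)) for _ in range(5)]
        a = ev.match_detections(gt, [])
        p, r = ev.detection_metrics(a)
        assert (p, r) == (1.0, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_formula_on_random_counts(self, seed):
        rng = np.random.default_rng(seed)
        gts, dets = random_scene(rng)
        a = ev.match_detections(gts, dets, 0.5)
        p, r = ev.detection_metrics(a)
        if a.tp + a.fp:
            assert p == pytest.approx(a.tp / (a.tp + a.fp))
        if a.n_gt:
            assert r == pytest.approx(a.tp / a.n_gt)


def oracle_ap(labels, scores, n_gt, grid=20001):
    """Brute-force rectangle integration of the interpolated PR curve."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    lab = np.asarray(labels, bool)[order]
    tp = np.cumsum(lab)
    fp = np.cumsum(~lab)
    rec = tp / n_gt
    prec = tp / (tp + fp)

    def p_interp(r):
        mask = rec >= r - 1e-12
        return prec[mask].max() if mask.any() else 0.0

    rmax = rec[-1] if len(rec) else 0.0
    rs = np.linspace(0, rmax, grid)[1:]
    return float(np.mean([p_interp(r) for r in rs]) * rmax) if rmax > 0 else 0.0


class TestInterpolatedAP:
    def test_ten_of_eleven_zero_fp(self):
        labels = [True] * 10
        scores = list(np.linspace(1, 0.5, 10))
        assert ev.interpolated_ap(labels, scores, 11) == pytest.approx(10 / 11)

    def test_all_found_no_fp_is_one(self):
        assert ev.interpolated_ap([True] * 7, list(range(7)), 7) == pytest.approx(1.0)

    def test_zero_gt_rejected(self):
        with pytest.raises(ValueError):
            ev.interpolated_ap([True], [1.0], 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_numeric_integration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        n_gt = int(rng.integers(1, 30))
        labels = list(rng.random(n) < 0.5)
        if sum(labels) > n_gt:
            n_gt = sum(labels)
        scores = list(rng.normal(size=n))
        got = ev.interpolated_ap(labels, scores, n_gt)
        assert got == pytest.approx(oracle_ap(labels, scores, n_gt), abs=2e-3)


class TestLandmarkError:
    @staticmethod
    def face(dx=0.0, dy=0.0, iod=50.0):
        gt = FaceAnnotation(
            box=Box(0, 0, 100, 100),
            landmarks={"leye": Point2D(25, 40), "reye": Point2D(25 + iod, 40)},
        )
        pred = {k: Point2D(p.x + dx, p.y + dy) for k, p in gt.landmarks.items()}
        return pred, gt

    def test_exact_prediction_zero_error(self):
        pred, gt = self.face()
        out = ev.landmark_error([pred], [gt])
        assert out.mean == 0.0

    def test_eight_percent_offset(self):
        pred, gt = self.face(dx=4.0)  # 8% of iod 50
        out = ev.landmark_error([pred], [gt])
        assert out.mean == pytest.approx(0.08)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_formula(self, seed):
        rng = np.random.default_rng(seed)
        preds, gts, expect = [], [], []
        for _ in range(6):
            iod = float(rng.uniform(20, 80))
            gt = FaceAnnotation(
                box=Box(0, 0, 200, 200),
                landmarks={"leye": Point2D(50, 60), "reye": Point2D(50 + iod, 60)},
            )
            offs = rng.normal(0, 3, (2, 2))
            pred = {
                "leye": Point2D(50 + offs[0, 0], 60 + offs[0, 1]),
                "reye": Point2D(50 + iod + offs[1, 0], 60 + offs[1, 1]),
            }
            preds.append(pred)
            gts.append(gt)
            expect.append(np.mean(np.linalg.norm(offs, axis=1)) / iod)
        out = ev.landmark_error(preds, gts)
        assert out.mean == pytest.approx(np.mean(expect))
        assert out.sd == pytest.approx(np.std(expect, ddof=1))

    def test_zero_iod_excluded_with_warning(self):
        pred, gt = self.face()
        bad = FaceAnnotation(box=Box(0, 0, 10, 10), landmarks={"leye": Point2D(5, 5), "reye": Point2D(5, 5)})
        with pytest.warns(UserWarning, match="excluded"):
            out = ev.landmark_error([pred, pred], [gt, bad])
        assert len(out.distances) == 1 and out.n_excluded == 1


class TestBuildPairSet:
    def test_exhaustive_two_by_two(self):
        pairs = ev.build_pair_set(["A", "A", "B", "B"], 2, seed=0)
        match = {p.key() for p in pairs if p.is_match}
        non = {p.key() for p in pairs if not p.is_match}
        assert match == {(0, 1), (2, 3)}
        assert len(non) == 2 and all(k not in match for k in non)

    @pytest.mark.parametrize("seed", range(10))
    def test_constraints_on_random_datasets(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"i{int(rng.integers(0, 6))}" for _ in range(int(rng.integers(6, 30)))]
        if len(set(labels)) < 2:
            labels += ["iA", "iA", "iB"]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairs = ev.build_pair_set(labels, int(rng.integers(1, 40)), seed=seed)
        keys = [p.key() for p in pairs]
        assert len(keys) == len(set(keys))  # unique
        for p in pairs:
            assert p.a != p.b
            assert (labels[p.a] == labels[p.b]) == p.is_match
        n_match = sum(p.is_match for p in pairs)
        assert n_match == len(pairs) - n_match  # balanced

    def test_andean_scale_230_pairs(self):
        rng = np.random.default_rng(1)
        # 121 chips over 25 identities, each with >= 2 chips
        labels = []
        for i in range(25):
            labels += [f"b{i:02d}"] * (2 + int(rng.integers(0, 7)))
        labels = labels[:121]
        pairs = ev.build_pair_set(labels, 230, seed=2)
        assert sum(p.is_match for p in pairs) == 230
        assert sum(not p.is_match for p in pairs) == 230

    def test_single_chip_identities_rejected(self):
        with pytest.raises(ValueError, match="matching"):
            ev.build_pair_set(["A", "B", "C"], 5, seed=0)


class TestVerificationMetrics:
    def test_perfect_separation(self):
        pairs = [ChipPair(0, 1, True), ChipPair(2, 3, True), ChipPair(0, 2, False), ChipPair(1, 3, False)]
        out = ev.verification_metrics(pairs, [0.1, 0.2, 0.9, 0.8], 0.5)
        assert out.accuracy == 1.0 and out.f1 == 1.0

    def test_printed_rates_compose_to_printed_accuracy(self):
        """TPR 85.2% with TNR 96.5% at equal class ratios gives 90.9%."""
        n = 1000
        d_match = [0.1] * 852 + [0.9] * 148
        d_non = [0.9] * 965 + [0.1] * 35
        pairs = [ChipPair(2 * i, 2 * i + 1, True) for i in range(n)] + [
            ChipPair(2 * (n + i), 2 * (n + i) + 1, False) for i in range(n)
        ]
        out = ev.verification_metrics(pairs, d_match + d_non, 0.5)
        assert out.tpr == pytest.approx(0.852)
        assert out.tnr == pytest.approx(0.965)
        assert ev.percent(out.accuracy) == 90.9

    def test_balanced_accuracy_identity_holds(self):
        rng = np.random.default_rng(0)
        pairs = [ChipPair(2 * i, 2 * i + 1, bool(i % 2)) for i in range(40)]
        d = list(rng.uniform(0, 1, 40))
        out = ev.verification_metrics(pairs, d, 0.5)
        pos = sum(p.is_match for p in pairs) / len(pairs)
        assert out.accuracy == pytest.approx(out.tpr * pos + out.tnr * (1 - pos))

    def test_null_distances_near_half(self):
        rng = np.random.default_rng(1)
        n = 5000
        pairs = [ChipPair(2 * i, 2 * i + 1, i < n // 2) for i in range(n)]
        d = list(rng.uniform(0, 1, n))
        out = ev.verification_metrics(pairs, d, 0.5)
        assert abs(out.accuracy - 0.5) <= 0.02


class TestRoc:
    def test_perfect_separation_hits_corner(self):
        pairs = [ChipPair(0, 1, True), ChipPair(2, 3, True), ChipPair(0, 2, False)]
        pts = ev.roc_points(pairs, [0.1, 0.2, 0.9])
        assert (0.0, 1.0) in {(p[0], p[1]) for p in pts}

    def test_degenerate_identical_distances_diagonal(self):
        pairs = [ChipPair(0, 1, True), ChipPair(0, 2, False)]
        pts = ev.roc_points(pairs, [0.5, 0.5])
        assert [(p[0], p[1]) for p in pts] == [(0.0, 0.0), (1.0, 1.0)]
        assert ev.roc_auc(pts) == pytest.approx(0.5)

    def test_monotone_tpr(self):
        rng = np.random.default_rng(2)
        pairs = [ChipPair(3 * i, 3 * i + 1, bool(rng.integers(0, 2))) for i in range(50)]
        if not any(p.is_match for p in pairs):
            pairs[0] = ChipPair(0, 1, True)
        pts = ev.roc_points(pairs, list(rng.uniform(0, 1, 50)))
        tprs = [p[1] for p in pts]
        fprs = [p[0] for p in pts]
        assert tprs == sorted(tprs)
        assert fprs == sorted(fprs)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_matches_sklearn(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        n = 60
        is_match = rng.integers(0, 2, n).astype(bool)
        if is_match.all() or not is_match.any():
            is_match[0] = ~is_match[1]
        d = rng.uniform(0, 1, n)
        pairs = [ChipPair(3 * i, 3 * i + 1, bool(m)) for i, m in enumerate(is_match)]
        auc = ev.roc_auc(ev.roc_points(pairs, list(d)))
        assert auc == pytest.approx(roc_auc_score(is_match, -d))


class TestFolds:
    def test_fold_sizes_609_by_chip(self):
        labels = [f"id{i:02d}" for i in range(29) for _ in range(21)]  # 609 chips
        folds = ev.make_folds(labels, 5, "by_chip", seed=0)
        assert float(np.mean([len(f) for f in folds])) == pytest.approx(121.8)

    def test_by_id_five_identities_one_per_fold(self):
        labels = ["A", "A", "B", "C", "D", "E", "E"]
        folds = ev.make_folds(labels, 5, "by_id", seed=1)
        labels_arr = np.asarray(labels)
        for f in folds:
            assert len(set(labels_arr[f])) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_by_id_never_splits_an_identity_and_partitions(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"i{int(rng.integers(0, 9))}" for _ in range(int(rng.integers(20, 60)))]
        k = 1 + len(set(labels)) // 2
        folds = ev.make_folds(labels, max(2, k), "by_id", seed=seed)
        seen = {}
        all_idx = []
        for fi, f in enumerate(folds):
            all_idx.extend(f.tolist())
            for i in f:
                ident = labels[i]
                assert seen.setdefault(ident, fi) == fi
        assert sorted(all_idx) == list(range(len(labels)))

    def test_by_chip_partitions_and_stratifies(self):
        labels = ["A"] * 10 + ["B"] * 10
        folds = ev.make_folds(labels, 5, "by_chip", seed=3)
        all_idx = sorted(i for f in folds for i in f.tolist())
        assert all_idx == list(range(20))
        for f in folds:
            arr = [labels[i] for i in f]
            assert arr.count("A") == 2 and arr.count("B") == 2

    def test_too_few_identities_rejected(self):
        with pytest.raises(ValueError, match="identities"):
            ev.make_folds(["A", "A", "B"], 5, "by_id", seed=0)

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            ev.make_folds(["A", "B"], 1, "by_chip", seed=0)


class TestCrossval:
    @staticmethod
    def features_labels(seed=0):
        rng = np.random.default_rng(seed)
        labels = [f"i{j}" for j in range(8) for _ in range(6)]
        centers = {l: rng.normal(0, 1, 12) for l in set(labels)}
        X = np.vstack([centers[l] + rng.normal(0, 0.1, 12) for l in labels])
        return X, labels

    def test_deterministic_given_seed(self):
        X, labels = self.features_labels()
        a = ev.crossval_verification(X, labels, 4, "by_chip", seed=5, n_pairs_per_class=20)
        b = ev.crossval_verification(X, labels, 4, "by_chip", seed=5, n_pairs_per_class=20)
        assert a.to_dict() == b.to_dict()

    def test_fold_sizes_partition(self):
        X, labels = self.features_labels(1)
        out = ev.crossval_verification(X, labels, 4, "by_id", seed=0, n_pairs_per_class=20)
        assert sum(int(round(n)) for n in [out.mean_test_n] * len(out.per_fold)) == pytest.approx(
            len(labels), abs=len(out.per_fold)
        )


class TestIdentificationAccuracy:
    @pytest.mark.parametrize("correct,total,pct", [(104, 121, 86.0), (108, 121, 89.3), (0, 7, 0.0)])
    def test_printed_ratios(self, correct, total, pct):
        truth = [f"t{i}" for i in range(total)]
        preds = [truth[i] if i < correct else "wrong" for i in range(total)]
        ratio, p = ev.identification_accuracy(preds, truth)
        assert ratio == pytest.approx(correct / total)
        assert p == pct

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.identification_accuracy([], [])


class TestEndToEnd:
    def test_paper_style_accounting(self):
        e = ev.EndToEndEval(
            n_images=121,
            faces_detected=120,
            faces_missed=1,
            erroneous_detections=2,
            correct_ids=104,
            accuracy_over_images=104 / 121,
            accuracy_over_detected=104 / 120,
        )
        d = e.to_dict()
        assert d["total_detections"] == 122
        assert d["accuracy_over_images_pct"] == 86.0
        assert d["accuracy_over_detected_pct"] == 86.7

    def test_pipeline_accounting_invariants(self, trained_small, small_split):
        _, test = small_split
        out = ev.end_to_end_evaluate(
            trained_small.detector,
            trained_small.shape,
            trained_small.chip_spec,
            trained_small.embedder,
            trained_small.classifier,
            test,
        )
        assert out.total_detections == out.faces_detected + out.erroneous_detections
        assert out.faces_detected + out.faces_missed == out.n_images
        assert 0.0 <= out.accuracy_over_images <= out.accuracy_over_detected <= 1.0
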