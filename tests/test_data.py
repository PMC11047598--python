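"""Annotation conversion, splitting, augmentation expansion, scenes, mosaic."""
import numpy as np
import pytest

from repacid.data import (DEFAULT_CLASS_COUNTS, CocoAnnotation, ImageRecord,
                          SceneSpec, YoloLabel, coco_to_yolo,
                          expand_with_augmentation, flip_labels,
                          generate_scene, make_dataset, materialize,
                          mosaic_combine, read_coco_json, read_yolo_labels,
                          scene_geometry, split_dataset, write_coco_json,
                          write_yolo_labels, yolo_to_coco)
from repacid.evaluation import kmeans_anchors


class TestAnnotationConversion:
    def test_hand_case(self):
        ann = CocoAnnotation(0, 100, 100, 2, (10, 20, 30, 40))
        l = coco_to_yolo(ann)
        assert (l.cx, l.cy, l.w, l.h) == pytest.approx((0.25, 0.40, 0.30, 0.40))
        assert l.cls == 2

    def test_full_frame_box(self):
        ann = CocoAnnotation(0, 2560, 1920, 0, (0, 0, 2560, 1920))
        l = coco_to_yolo(ann)
        assert (l.cx, l.cy, l.w, l.h) == pytest.approx((0.5, 0.5, 1.0, 1.0))

    def test_roundtrip_random(self, rng):
        for _ in range(50):
            W, H = int(rng.integers(100, 5000)), int(rng.integers(100, 3000))
            w = rng.uniform(1, W / 2)
            h = rng.uniform(1, H / 2)
            x = rng.uniform(0, W - w)
            y = rng.uniform(0, H - h)
            ann = CocoAnnotation(3, W, H, 1, (x, y, w, h))
            back = yolo_to_coco(coco_to_yolo(ann), W, H, image_id=3)
            np.testing.assert_allclose(back.bbox, ann.bbox, atol=1e-9 * max(W, H))

    def test_out_of_bounds_clamped_with_warning(self):
        ann = CocoAnnotation(0, 100, 100, 0, (-10, 5, 30, 40))
        with pytest.warns(UserWarning, match="clamping"):
            l = coco_to_yolo(ann)
        assert l.cx == pytest.approx(0.10)      # clamped to [0, 20] wide
        with pytest.raises(ValueError):
            coco_to_yolo(ann, clamp=False)

    def test_label_file_roundtrip(self, tmp_path):
        labels = [YoloLabel(0, 0.25, 0.4, 0.3, 0.4), YoloLabel(6, 0.5, 0.5, 1, 1)]
        p = tmp_path / "img.txt"
        write_yolo_labels(p, labels)
        back = read_yolo_labels(p)
        assert len(back) == 2 and back[0].cls == 0 and back[1].cls == 6
        assert back[0].cx == pytest.approx(0.25, abs=1e-6)

    def test_coco_json_roundtrip(self, tmp_path):
        anns = [CocoAnnotation(0, 2560, 1920, 3, (10, 20, 300, 200)),
                CocoAnnotation(1, 4992, 2808, 5, (5, 5, 50, 60))]
        p = tmp_path / "ann.json"
        write_coco_json(p, anns)
        back = read_coco_json(p)
        assert back == anns


class TestSplit:
    def test_ten_images_splits_8_1_1(self):
        by_class = {0: list(range(10))}
        tr, va, te = split_dataset(by_class, seed=0)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)
        assert sorted(tr + va + te) == list(range(10))

    def test_all_train_ratio(self):
        by_class = {0: list(range(7))}
        tr, va, te = split_dataset(by_class, ratios=(1.0, 0.0, 0.0), seed=0)
        assert (len(tr), len(va), len(te)) == (7, 0, 0)

    def test_composition_sums_preserved(self, rng):
        """Any composition of 1774 images splits with conserved totals."""
        sizes = [int(s) for s in rng.multinomial(1774, np.ones(7) / 7)]
        by_class = {c: [f"{c}-{i}" for i in range(n)] for c, n in enumerate(sizes)}
        tr, va, te = split_dataset(by_class, seed=1)
        assert len(tr) + len(va) + len(te) == 1774
        assert len(set(tr) | set(va) | set(te)) == 1774

    def test_reference_counts_reproduce_printed_totals(self):
        by_class = {c: list(range(n)) for c, n in enumerate(DEFAULT_CLASS_COUNTS)}
        tr, va, te = split_dataset(by_class, seed=0)
        assert (len(tr), len(va), len(te)) == (1423, 177, 174)

    def test_tiny_class_goes_to_train_with_warning(self):
        with pytest.warns(UserWarning, match="all assigned to train"):
            tr, va, te = split_dataset({0: [1, 2], 1: list(range(10))}, seed=0)
        assert len(tr) == 10 and len(va) == 1 and len(te) == 1


class TestAugmentationExpansion:
    @staticmethod
    def records(n):
        spec = SceneSpec(width=256, height=192, seed=1)
        return [ImageRecord(i, spec, [YoloLabel(0, 0.25, 0.4, 0.3, 0.4)])
                for i in range(n)]

    def test_count_multiplies_by_four(self):
        out = expand_with_augmentation(self.records(11))
        assert len(out) == 44
        assert sum(r.augmentation == "none" for r in out) == 11

    def test_printed_split_sizes_after_expansion(self):
        assert len(expand_with_augmentation(self.records(1423))) == 5692
        total = sum(len(expand_with_augmentation(self.records(n)))
                    for n in (1423, 177, 174))
        assert total == 7096

    def test_flip_mirrors_cx_only(self):
        l = YoloLabel(2, 0.25, 0.4, 0.3, 0.4)
        f = flip_labels([l])[0]
        assert (f.cx, f.cy, f.w, f.h) == pytest.approx((0.75, 0.4, 0.3, 0.4))
        assert f.cls == 2

    def test_materialized_variants_differ_from_original(self):
        base = self.records(1)
        out = expand_with_augmentation(base)
        img0, _ = materialize(out[0], render_size=(64, 64))
        for r in out[1:]:
            img, labels = materialize(r, render_size=(64, 64))
            assert img.shape == img0.shape
            assert not np.array_equal(img, img0)


class TestSceneGenerator:
    def test_same_seed_byte_identical(self):
        spec = SceneSpec(seed=42, class_id=3)
        img1, ann1 = generate_scene(spec, render_size=(96, 96))
        img2, ann2 = generate_scene(spec, render_size=(96, 96))
        assert np.array_equal(img1, img2)
        assert [a.bbox for a in ann1] == [a.bbox for a in ann2]
        assert img1.dtype == np.uint8

    def test_zero_object_scene_is_empty_frame(self):
        img, anns = generate_scene(SceneSpec(seed=1, n_objects=0),
                                   render_size=(64, 64))
        assert anns == []
        assert img.shape == (64, 64, 3)

    def test_box_tight_around_rendered_foreground(self):
        spec = SceneSpec(seed=7, class_id=4, scale_range=(0.3, 0.4))
        size = 160
        img, anns = generate_scene(spec, render_size=(size, size))
        day, _ = generate_scene(SceneSpec(**{**spec.__dict__}), render_size=(size, size))
        x, y, w, h = anns[0].bbox
        # rendered silhouette must not extend beyond the analytic box by
        # more than pixel quantization
        assert 0 <= x and x + w <= size and 0 <= y and y + h <= size
        assert w > 8 and h > 8

    def test_night_scenes_darker(self):
        day = SceneSpec(seed=5, illumination="day")
        night = SceneSpec(seed=5, illumination="night")
        di, _ = generate_scene(day, render_size=(64, 64))
        ni, _ = generate_scene(night, render_size=(64, 64))
        assert ni.mean() < 0.6 * di.mean()

    def test_classes_render_distinct_silhouettes(self):
        imgs = [generate_scene(SceneSpec(seed=9, class_id=c),
                               render_size=(64, 64))[0] for c in range(7)]
        for i in range(7):
            for j in range(i + 1, 7):
                assert not np.array_equal(imgs[i], imgs[j])

    def test_generated_shapes_recoverable_by_kmeans(self, rng):
        """Boxes drawn from 4 configured scale modes cluster back within 10%."""
        modes = (0.12, 0.22, 0.32, 0.45)
        wh = []
        for i in range(600):
            m = modes[i % 4]
            spec = SceneSpec(640, 640, class_id=i % 7, seed=i,
                             scale_range=(m * 0.98, m * 1.02))
            for o in scene_geometry(spec):
                _, _, w, h = o["bbox_norm"]
                wh.append([w * 640, h * 640])
        anchors = kmeans_anchors(np.array(wh), 4, seed=0)
        long_sides = np.sort(anchors.as_array().max(axis=1))
        expected = np.array(modes) * 640
        assert np.all(np.abs(long_sides - expected) / expected < 0.10)


class TestMosaic:
    @staticmethod
    def labelled(rng, value):
        img = np.full((64, 64, 3), value, dtype=np.uint8)
        return img, [YoloLabel(0, 0.5, 0.5, 0.4, 0.4)]

    def test_center_split_identical_inputs_scale_half(self, rng):
        four = [self.labelled(rng, 100)] * 4
        canvas, labels = mosaic_combine(four, out_size=128, split_point=(64, 64))
        assert canvas.shape == (128, 128, 3)
        assert len(labels) == 4
        for l in labels:
            assert (l.w, l.h) == pytest.approx((0.2, 0.2))

    def test_interior_box_survives_once(self, rng):
        img = np.zeros((64, 64, 3), np.uint8)
        four = [(img, [YoloLabel(1, 0.5, 0.5, 0.2, 0.2)]),
                (img, []), (img, []), (img, [])]
        canvas, labels = mosaic_combine(four, out_size=128, split_point=(64, 64))
        assert len(labels) == 1 and labels[0].cls == 1

    def test_random_collages_respect_bounds_and_visibility(self, rng):
        img = np.zeros((48, 48, 3), np.uint8)
        for seed in range(20):
            four = [(img, [YoloLabel(0, float(rng.uniform(0.2, 0.8)),
                                     float(rng.uniform(0.2, 0.8)),
                                     float(rng.uniform(0.1, 0.5)),
                                     float(rng.uniform(0.1, 0.5)))])
                    for _ in range(4)]
            _, labels = mosaic_combine(four, seed=seed, out_size=96)
            for l in labels:
                assert 0 <= l.cx - l.w / 2 + 1e-9 and l.cx + l.w / 2 <= 1 + 1e-9
                assert 0 <= l.cy - l.h / 2 + 1e-9 and l.cy + l.h / 2 <= 1 + 1e-9
                assert l.w > 0 and l.h > 0

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError):
            mosaic_combine([(np.zeros((8, 8, 3), np.uint8), [])] * 3)


def test_make_dataset_manifest_counts_and_determinism():
    a = make_dataset((5, 6), seed=11)
    b = make_dataset((5, 6), seed=11)
    assert [len(v) for v in a.values()] == [5, 6]
    for cls in a:
        for ra, rb in zip(a[cls], b[cls]):
            assert ra.scene == rb.scene
            assert [l.as_array().tolist() for l in ra.labels] == \
                   [l.as_array().tolist() for l in rb.labels]
    ids = [r.image_id for v in a.values() for r in v]
    assert len(set(ids)) == len(ids)
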