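import numpy as np
import pytest

from skullmark import synthetic as syn
from skullmark.augment import (AugmentDraw, AugmentSpec, CvLayout, augment_once,
                               expand_dataset, make_cv_folds, transform_point,
                               write_fold_manifest)
from skullmark.errors import AugmentationError, SplitError
from skullmark.experiments import ground_truth_window
from skullmark.heatmap import HeatmapConfig, decode_heatmap, make_label
from skullmark.roi import extract_crop


@pytest.fixture(scope="module")
def scene_and_window():
    sc = syn.generate_scene(preset=syn.TINY, seed=21)
    return sc, ground_truth_window(sc, syn.TINY)


IDENTITY = AugmentDraw(flip_h=False, flip_v=False, angle_deg=0.0, shift=(0.0, 0.0))


class TestAugmentOnce:
    def test_identity_draw_reproduces_plain_crop(self, scene_and_window):
        sc, win = scene_and_window
        crop, lm, used, _ = augment_once(sc.image, sc.landmarks, win,
                                         AugmentSpec(seed=0), 0, draw=IDENTITY)
        plain = extract_crop(sc.image, win)
        assert np.allclose(crop, plain.astype(np.float32))
        expect = win.landmarks_to_crop(sc.landmarks)
        assert np.allclose(lm.as_array(), expect.as_array(), atol=1e-9)

    def test_horizontal_flip_reflects_columns(self, scene_and_window):
        sc, win = scene_and_window
        d = AugmentDraw(flip_h=True, flip_v=False, angle_deg=0.0, shift=(0.0, 0.0))
        crop, lm, _, _ = augment_once(sc.image, sc.landmarks, win,
                                      AugmentSpec(seed=0), 0, draw=d)
        base = win.landmarks_to_crop(sc.landmarks)
        S = win.crop_size
        assert lm.bregma[0] == pytest.approx(base.bregma[0])
        assert lm.bregma[1] == pytest.approx(S - 1 - base.bregma[1])

    def test_rotation_matches_closed_form(self):
        # 90 deg rotation about the crop centre of a 640 crop
        d = AugmentDraw(flip_h=False, flip_v=False, angle_deg=90.0, shift=(0, 0))
        q = transform_point((100.0, 200.0), d, 640)
        centre = np.array([319.5, 319.5])
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        expect = R @ (np.array([100.0, 200.0]) - centre) + centre
        assert np.abs(q - expect).max() < 0.5

    def test_rotated_image_follows_landmarks(self, scene_and_window):
        # drop a bright dot at bregma and check it lands on the transformed point
        sc, win = scene_and_window
        img = np.zeros_like(sc.image)
        r, c = (int(round(v)) for v in sc.landmarks.bregma)
        img[r - 1:r + 2, c - 1:c + 2] = 255
        d = AugmentDraw(flip_h=True, flip_v=False, angle_deg=57.0, shift=(0.02, -0.03))
        crop, lm, _, _ = augment_once(img, sc.landmarks, win,
                                      AugmentSpec(seed=0), 0, draw=d)
        peak = np.unravel_index(np.argmax(crop.mean(axis=2)), crop.shape[:2])
        assert np.abs(np.array(peak) - np.array(lm.bregma)).max() <= 1.5

    def test_label_consistency_over_seeded_draws(self, scene_and_window):
        sc, win = scene_and_window
        spec = AugmentSpec(seed=77)
        cfg = HeatmapConfig(sigma=6.0)
        for k in range(50):
            _, lm, used, _ = augment_once(sc.image, sc.landmarks, win, spec, k)
            label = make_label((used.crop_size, used.crop_size), lm, cfg,
                               frame="crop")
            dec = decode_heatmap(label.values, frame="crop")
            assert np.abs(dec.as_array() - lm.as_array()).max() <= 1.0

    def test_expelling_draw_raises_after_retries(self, scene_and_window):
        sc, win = scene_and_window
        bad = AugmentDraw(flip_h=False, flip_v=False, angle_deg=0.0,
                          shift=(0.9, 0.9))  # pixel-mode shift pushes landmarks out
        spec = AugmentSpec(seed=0, mode="pixel")
        with pytest.raises(AugmentationError):
            augment_once(sc.image, sc.landmarks, win, spec, 0, draw=bad)

    def test_augmentation_log_written(self, scene_and_window, tmp_path):
        import pandas as pd
        from skullmark.augment import draw_record, write_augmentation_log
        sc, win = scene_and_window
        spec = AugmentSpec(seed=3)
        records = []
        for k in range(4):
            _, _, _, d = augment_once(sc.image, sc.landmarks, win, spec, k)
            records.append(draw_record("scene_0", k, spec.seed, d))
        p = tmp_path / "log.csv"
        write_augmentation_log(p, records)
        back = pd.read_csv(p)
        assert len(back) == 4 and "angle_deg" in back.columns

    def test_draws_are_reproducible(self, scene_and_window):
        sc, win = scene_and_window
        spec = AugmentSpec(seed=5)
        a = augment_once(sc.image, sc.landmarks, win, spec, 3)
        b = augment_once(sc.image, sc.landmarks, win, spec, 3)
        assert np.array_equal(a[0], b[0])
        assert a[3] == b[3]


class TestExpandDataset:
    def test_published_counts(self):
        spec = AugmentSpec(copies_per_image=100, seed=0)
        assert len(expand_dataset([f"im{i}" for i in range(80)], spec)) == 8000
        assert len(expand_dataset([f"im{i}" for i in range(60)], spec)) == 6000

    def test_single_copy_is_input_sized(self):
        spec = AugmentSpec(copies_per_image=1, seed=0)
        plan = expand_dataset(["a", "b", "c"], spec)
        assert list(plan["image_id"]) == ["a", "b", "c"]

    def test_per_copy_seeds_are_distinct_and_stable(self):
        spec = AugmentSpec(copies_per_image=5, seed=2)
        p1 = expand_dataset(["a", "b"], spec)
        p2 = expand_dataset(["a", "b"], spec)
        assert p1.equals(p2)
        assert p1["draw_seed"].nunique() == len(p1)


@pytest.fixture(scope="module")
def plan93():
    table = syn.generate_annotations(93, preset=syn.TINY, seed=0)
    return make_cv_folds(table, CvLayout(), seed=0)


class TestCvFolds:
    def test_published_subset_sizes(self, plan93):
        sizes = [len(s) for s in plan93.subsets]
        assert sizes == [20, 20, 20, 20, 13]

    def test_fold_composition(self, plan93):
        for fold in plan93.folds:
            assert len(fold["train"]) == 60
            assert len(fold["val"]) == 20
            assert len(fold["test"]) == 13

    def test_validation_rotates_over_first_four_subsets(self, plan93):
        vals = [set(f["val"]) for f in plan93.folds]
        union = set().union(*vals)
        assert len(union) == 80
        for a, b in zip(vals, vals[1:]):
            assert not (a & b)

    def test_test_subset_fixed_across_folds(self, plan93):
        tests = {tuple(sorted(f["test"])) for f in plan93.folds}
        assert len(tests) == 1

    def test_no_leakage(self, plan93):
        test_ids = set(plan93.folds[0]["test"])
        for fold in plan93.folds:
            assert not (test_ids & set(fold["train"]))
            assert not (test_ids & set(fold["val"]))

    def test_manifest_and_yaml(self, plan93, tmp_path):
        m = plan93.manifest()
        assert set(m["role"]) == {"train", "val", "test"}
        assert len(m) == 4 * 93
        write_fold_manifest(tmp_path / "folds.yaml", plan93)
        assert (tmp_path / "folds.yaml").exists()

    def test_too_few_images(self):
        table = syn.generate_annotations(4, preset=syn.TINY, seed=0)
        with pytest.raises(SplitError):
            make_cv_folds(table, CvLayout(), seed=0)
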