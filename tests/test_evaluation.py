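import numpy as np
import pytest

from skullmark import synthetic as syn
from skullmark.errors import CalibrationError, FrameError, InvalidInputError
from skullmark.evaluation import (LocalizationResult, ScaleCalibration,
                                  axis_decomposition, evaluate_pipeline,
                                  localization_error, pixel_to_um,
                                  plot_error_scatter, results_to_frame,
                                  sigma_sweep, summarize)
from skullmark.frames import LandmarkSet
from skullmark.roi import OtsuSkullDetector


class TestCalibration:
    def test_published_conversion_arithmetic(self):
        cal = ScaleCalibration(physical_distance_um=4200.0, pixel_distance=163.20)
        assert round(cal.um_per_pixel, 2) == 25.74

    def test_zero_error_maps_to_zero(self):
        assert pixel_to_um(0.0, ScaleCalibration()) == 0.0

    def test_plain_multiplication(self):
        cal = ScaleCalibration(physical_distance_um=25.735 * 163.2,
                               pixel_distance=163.2)
        assert pixel_to_um(10, cal) == pytest.approx(257.35)

    def test_um_scales_linearly_with_physical_distance(self):
        a = ScaleCalibration(physical_distance_um=4200, pixel_distance=163.2)
        b = ScaleCalibration(physical_distance_um=8400, pixel_distance=163.2)
        assert pixel_to_um(7.3, b) == pytest.approx(2 * pixel_to_um(7.3, a))

    def test_from_landmark_sets_uses_mean_distance(self):
        sets = [LandmarkSet((0, 0), (0, 100), frame="crop"),
                LandmarkSet((0, 0), (0, 200), frame="crop")]
        cal = ScaleCalibration.from_landmark_sets(sets, physical_distance_um=4200)
        assert cal.pixel_distance == pytest.approx(150.0)

    def test_invalid_calibration(self):
        with pytest.raises(CalibrationError):
            ScaleCalibration(physical_distance_um=0, pixel_distance=100)


class TestErrors:
    def test_perfect_prediction_is_zero(self):
        lm = LandmarkSet((10, 10), (50, 10), frame="crop")
        assert localization_error(lm, lm) == {"bregma": 0.0, "lambda": 0.0}

    def test_three_four_five_triangle(self):
        t = LandmarkSet((10, 10), (50, 10), frame="crop")
        p = LandmarkSet((13, 14), (50, 10), frame="crop")
        e = localization_error(p, t)
        assert e["bregma"] == pytest.approx(5.0)

    def test_batch_mean_and_max_match_bruteforce(self, rng):
        errs = []
        for _ in range(13):
            t = LandmarkSet(tuple(rng.uniform(10, 100, 2)),
                            tuple(rng.uniform(110, 200, 2)), frame="crop")
            off = rng.normal(0, 3, 2)
            p = LandmarkSet(tuple(np.array(t.bregma) + off), t.lambda_, frame="crop")
            errs.append(localization_error(p, t)["bregma"])
        assert np.mean(errs) == pytest.approx(sum(errs) / 13)
        assert np.max(errs) == pytest.approx(sorted(errs)[-1])

    def test_frame_mismatch(self):
        a = LandmarkSet((1, 1), (2, 2), frame="crop")
        b = LandmarkSet((1, 1), (2, 2), frame="net")
        with pytest.raises(FrameError):
            localization_error(a, b)


class TestAxisDecomposition:
    PAIR = LandmarkSet((100, 50), (200, 50), frame="crop")  # axis along rows

    def test_error_parallel_to_axis_has_zero_left_right(self):
        th, lr = axis_decomposition((110, 50), (100, 50), self.PAIR)
        assert lr == pytest.approx(0.0)
        assert abs(th) == pytest.approx(10.0)

    def test_row_aligned_axis_returns_raw_components(self):
        th, lr = axis_decomposition((103, 54), (100, 50), self.PAIR)
        assert (abs(th), abs(lr)) == (pytest.approx(3.0), pytest.approx(4.0))

    def test_pythagoras_over_random_draws(self, rng):
        for _ in range(100):
            t = rng.uniform(0, 640, 2)
            p = t + rng.normal(0, 5, 2)
            th, lr = axis_decomposition(p, t, self.PAIR)
            assert th**2 + lr**2 == pytest.approx(float(np.sum((p - t) ** 2)),
                                                  rel=1e-6)

    def test_coincident_pair_rejected(self):
        pair = LandmarkSet.unchecked((1.0, 1.0), (1.0, 1.0), "crop")
        with pytest.raises(InvalidInputError):
            axis_decomposition((0, 0), (1, 1), pair)


class _ConstantModel:
    trained = True

    def __init__(self, n):
        self._n = n

    def forward(self, x, train=False):
        return np.full((len(x), 2, self._n, self._n), 0.5, np.float32)


class TestPipelineBookkeeping:
    def test_row_counts_and_failure_tally(self, rng):
        scenes = [syn.generate_scene(preset=syn.TINY, seed=300 + i)
                  for i in range(3)]
        # a noise 'scene' the detector must refuse
        noise = syn.AnnotatedImage(
            image=rng.integers(0, 255, scenes[0].image.shape).astype(np.uint8),
            bbox=scenes[0].bbox, landmarks=scenes[0].landmarks,
            params=scenes[0].params)
        results, summary = evaluate_pipeline(
            scenes + [noise], OtsuSkullDetector(), _ConstantModel(64), syn.TINY)
        assert summary["n_failed"] == 1
        assert len(results) == 2 * 3  # two landmarks per successful image
        assert summary["n_results"] + 2 * summary["n_failed"] == 2 * 4

    def test_scatter_export(self, tmp_path):
        results = [LocalizationResult("im0", "bregma", (1, 2), (1, 1), 1.0,
                                      25.7, (1.0, 0.0)),
                   LocalizationResult("im0", "lambda", (5, 5), (4, 4), 1.4,
                                      36.1, (1.0, 1.0))]
        out = tmp_path / "scatter.png"
        plot_error_scatter(results, out)
        assert out.stat().st_size > 0
        frame = results_to_frame(results)
        assert list(frame["landmark"]) == ["bregma", "lambda"]

    def test_export_writes_csv_json_png(self, tmp_path):
        from skullmark.evaluation import export_results
        results = [LocalizationResult("im0", "bregma", (1, 2), (1, 1), 1.0,
                                      25.7, (1.0, 0.0))]
        export_results(tmp_path / "out", results, summarize(results))
        for name in ("results.csv", "summary.json", "scatter.png"):
            assert (tmp_path / "out" / name).exists()

    def test_summary_handles_empty(self):
        s = summarize([], n_failed=2)
        assert s["n_failed"] == 2 and np.isnan(s["bregma_mean_error_px"])


class TestQuantizationFloor:
    def test_perfect_heatmap_error_bounded_by_decode_quantum(self, rng):
        # a model that outputs the exact label still quantises to integer
        # net pixels; after the 2.5x scale the crop error stays <= 2.5 px
        from skullmark.frames import LandmarkSet
        from skullmark.heatmap import HeatmapConfig, decode_heatmap, make_label
        cfg = HeatmapConfig(sigma=5.0)
        for _ in range(50):
            b = rng.uniform(5, 58, 2)
            l = rng.uniform(5, 58, 2)
            lm = LandmarkSet(tuple(b), tuple(l), frame="net")
            dec = decode_heatmap(make_label((64, 64), lm, cfg, frame="net").values)
            err = np.linalg.norm((dec.as_array() - lm.as_array()) * 2.5, axis=1)
            assert err.max() <= 2.5


class TestSigmaSweepShape:
    def test_single_sigma_single_column(self):
        table = sigma_sweep(sigmas=(20.0,), seed=0, n_train_scenes=4, copies=1,
                            n_val_scenes=2, n_test_scenes=2, epochs=1)
        assert list(table.columns) == [20.0]
        assert "bregma_mean_error_px" in table.index
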