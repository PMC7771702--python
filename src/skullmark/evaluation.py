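"""Localization-error metrics and end-to-end pipeline evaluation.

Errors are measured in the crop frame (the 640 x 640 full-resolution
crop for the full preset), the frame in which the bregma-lambda
distance of ~163 px corresponds to the anatomical 4.2 mm, and converted
to micrometres with a per-dataset calibration.  Each error vector is
also decomposed along the skull's own axes: the tail-head direction
(the ground-truth bregma-lambda axis) and the left-right direction
perpendicular to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import CalibrationError, DetectionError, FrameError, InvalidInputError
from .frames import LandmarkSet
from .roi import detect_skull, downsample, extract_net_input
from .fcn import predict_landmarks

LANDMARK_NAMES = ("bregma", "lambda")


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-micrometre conversion in the evaluation frame.

    The anatomical bregma-lambda distance (4.2 mm in adult mice) divided
    by its pixel measurement gives micrometres per pixel; the published
    measurement of 163.20 px yields 25.74 um/px.
    """

    physical_distance_um: float = 4200.0
    pixel_distance: float = 163.20

    def __post_init__(self):
        if not (self.physical_distance_um > 0 and self.pixel_distance > 0):
            raise CalibrationError("calibration distances must be positive")

    @property
    def um_per_pixel(self) -> float:
        return self.physical_distance_um / self.pixel_distance

    @classmethod
    def from_landmark_sets(cls, sets: Iterable[LandmarkSet],
                           physical_distance_um: float = 4200.0) -> "ScaleCalibration":
        """Calibrate from the mean ground-truth pixel distance of a test set."""
        dists = [float(np.linalg.norm(np.asarray(s.bregma) - np.asarray(s.lambda_)))
                 for s in sets]
        if not dists:
            raise CalibrationError("no landmark sets supplied")
        return cls(physical_distance_um=physical_distance_um,
                   pixel_distance=float(np.mean(dists)))


def pixel_to_um(error_px: float, cal: ScaleCalibration) -> float:
    """Convert a pixel error to micrometres."""
    conv = cal.um_per_pixel
    if conv <= 0:
        raise CalibrationError(f"non-positive conversion {conv}")
    return float(error_px) * conv


def localization_error(pred: LandmarkSet, truth: LandmarkSet) -> Dict[str, float]:
    """Euclidean distance per landmark; both sets must share a frame."""
    if pred.frame != truth.frame:
        raise FrameError(f"frame mismatch: {pred.frame!r} vs {truth.frame!r}")
    p, t = pred.as_array(), truth.as_array()
    d = np.linalg.norm(p - t, axis=1)
    return {"bregma": float(d[0]), "lambda": float(d[1])}


def axis_decomposition(pred, truth, truth_pair: LandmarkSet
                       ) -> Tuple[float, float]:
    """Signed (tail_head, left_right) components of the error vector.

    The tail-head unit axis is the normalised ground-truth bregma-lambda
    direction (pointing toward bregma, i.e. the head); left-right is its
    perpendicular.  The squared components always sum to the squared
    Euclidean error.
    """
    b, l = np.asarray(truth_pair.bregma, float), np.asarray(truth_pair.lambda_, float)
    axis = b - l
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise InvalidInputError("coincident bregma/lambda cannot define an axis")
    u = axis / norm
    v = np.array([-u[1], u[0]])
    e = np.asarray(pred, float) - np.asarray(truth, float)
    return float(e @ u), float(e @ v)


@dataclass(frozen=True)
class LocalizationResult:
    image_id: str
    landmark: str
    predicted: Tuple[float, float]
    true: Tuple[float, float]
    error_px: float
    error_um: float
    axis_components: Tuple[float, float]   # (tail_head, left_right)


def results_to_frame(results: Sequence[LocalizationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "image_id": r.image_id, "landmark": r.landmark,
        "pred_row": r.predicted[0], "pred_col": r.predicted[1],
        "true_row": r.true[0], "true_col": r.true[1],
        "error_px": r.error_px, "error_um": r.error_um,
        "err_tail_head": r.axis_components[0],
        "err_left_right": r.axis_components[1],
    } for r in results])


def summarize(results: Sequence[LocalizationResult], n_failed: int = 0) -> dict:
    """Mean/max error per landmark in px and um, plus the failure tally."""
    out = {"n_results": len(results), "n_failed": int(n_failed), "frame": "crop"}
    for name in LANDMARK_NAMES:
        errs = [r.error_px for r in results if r.landmark == name]
        ums = [r.error_um for r in results if r.landmark == name]
        out[f"{name}_mean_error_px"] = float(np.mean(errs)) if errs else float("nan")
        out[f"{name}_max_error_px"] = float(np.max(errs)) if errs else float("nan")
        out[f"{name}_mean_error_um"] = float(np.mean(ums)) if ums else float("nan")
        out[f"{name}_max_error_um"] = float(np.max(ums)) if ums else float("nan")
    return out


def evaluate_pipeline(scenes, detector, model, preset, cal=None,
                      upscale_first: bool = False
                      ) -> Tuple[List[LocalizationResult], dict]:
    """Run stage one + stage two on annotated scenes and score the output.

    A scene where the detector refuses (no skull found) is excluded from
    the error statistics and counted in the failure tally instead of
    being assigned a penalty distance.
    """
    prepared = []  # (image_id, pred LandmarkSet, truth LandmarkSet) in crop frame
    n_failed = 0
    for i, scene in enumerate(scenes):
        image_id = f"scene_{i:05d}"
        try:
            lowres = downsample(scene.image, preset.downsample_factor)
            det = detect_skull(lowres, detector)
        except DetectionError:
            n_failed += 1
            continue
        net_img, window = extract_net_input(
            scene.image, det, factor=preset.downsample_factor,
            crop_size=preset.crop_size, net_size=preset.net_size)
        pred = predict_landmarks(model, net_img, window,
                                 upscale_first=upscale_first)
        truth = window.landmarks_to_crop(scene.landmarks)
        prepared.append((image_id, pred, truth))

    if cal is None and prepared:
        cal = ScaleCalibration.from_landmark_sets([t for _, _, t in prepared])
    results: List[LocalizationResult] = []
    for image_id, pred, truth in prepared:
        errs = localization_error(pred, truth)
        for name, p, t in zip(LANDMARK_NAMES,
                              (pred.bregma, pred.lambda_),
                              (truth.bregma, truth.lambda_)):
            comps = axis_decomposition(p, t, truth)
            results.append(LocalizationResult(
                image_id=image_id, landmark=name, predicted=tuple(p),
                true=tuple(t), error_px=errs[name],
                error_um=pixel_to_um(errs[name], cal),
                axis_components=comps))
    return results, summarize(results, n_failed=n_failed)


def sigma_sweep(sigmas: Sequence[float] = (5.0, 10.0, 20.0, 40.0),
                seed: int = 0, preset=None, **protocol_kwargs) -> pd.DataFrame:
    """Train one network per label width and tabulate test errors.

    ``sigmas`` are reference-frame (256-net) standard deviations; every
    run shares the same seed, scenes and schedule so the label width is
    the only difference.  Columns are sigmas, rows are mean/max error
    per landmark in crop-frame pixels.
    """
    from . import experiments  # local import; experiments builds on this module

    cols = {}
    for s in sigmas:
        out = experiments.run_protocol(seed=seed, sigma_ref=float(s),
                                       preset=preset, **protocol_kwargs)
        summ = out["summary"]
        cols[float(s)] = {
            "bregma_mean_error_px": summ["bregma_mean_error_px"],
            "lambda_mean_error_px": summ["lambda_mean_error_px"],
            "bregma_max_error_px": summ["bregma_max_error_px"],
            "lambda_max_error_px": summ["lambda_max_error_px"],
        }
    return pd.DataFrame(cols)


def export_results(out_dir, results: Sequence[LocalizationResult],
                   summary: dict) -> None:
    """Write results.csv (one row per image x landmark), summary.json and
    the error-scatter PNG into a directory."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_to_frame(results).to_csv(out / "results.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    plot_error_scatter(results, out / "scatter.png")


def plot_error_scatter(results: Sequence[LocalizationResult], path) -> None:
    """Per-landmark scatter of signed (left-right, tail-head) errors."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4.2), sharex=True, sharey=True)
    for ax, name in zip(axes, LANDMARK_NAMES):
        xs = [r.axis_components[1] for r in results if r.landmark == name]
        ys = [r.axis_components[0] for r in results if r.landmark == name]
        ax.scatter(xs, ys, s=18, c="k")
        ax.scatter([0], [0], marker="+", s=120, c="r")
        ax.set_title(name)
        ax.set_xlabel("left-right error (px)")
        ax.axhline(0, lw=0.5, c="0.7")
        ax.axvline(0, lw=0.5, c="0.7")
    axes[0].set_ylabel("tail-head error (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
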