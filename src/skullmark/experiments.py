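"""End-to-end training/evaluation protocols on synthetic scenes.

Glue that the examples, tests and the reproduction script share: build
augmented training arrays from synthetic scenes, train the network, and
score it on held-out scenes through the full two-stage pipeline.

The default *tiny protocol* is the CPU-scale replica of the published
experiment: 64 x 64 net input, quarter-width network, 200 augmented
training crops (50 scenes x 4 copies), 8 validation scenes, 30 epochs,
20 held-out test scenes, everything derived from one seed.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from .augment import AugmentSpec, augment_once
from .evaluation import evaluate_pipeline
from .fcn import FCNConfig, TrainConfig, train_fcn
from .frames import CropWindow, LandmarkSet, compute_crop_window
from .heatmap import HeatmapConfig, make_label, scaled_sigma
from .roi import OtsuSkullDetector, crop_to_net
from .synthetic import (TINY, Preset, child_seed, generate_scene,
                        sample_scene_params)

# namespacing offsets so train / val / test scene seeds never collide
_TRAIN_NS, _VAL_NS, _TEST_NS = 0, 500_000, 1_000_000


def ground_truth_window(scene, preset: Preset) -> CropWindow:
    """Crop window centred on the true skull bbox (stage-one oracle)."""
    return compute_crop_window(scene.bbox, scene.image.shape[:2],
                               crop_size=preset.crop_size,
                               net_size=preset.net_size)


def _net_pair(crop: np.ndarray, lm_crop: LandmarkSet, preset: Preset,
              sigma: float) -> Tuple[np.ndarray, np.ndarray]:
    """(input, label) arrays in the net frame for one crop."""
    scale = preset.crop_size / preset.net_size
    x = crop_to_net(crop, preset.net_size).transpose(2, 0, 1)
    lm_net = LandmarkSet(
        bregma=(lm_crop.bregma[0] / scale, lm_crop.bregma[1] / scale),
        lambda_=(lm_crop.lambda_[0] / scale, lm_crop.lambda_[1] / scale),
        frame="net")
    label = make_label((preset.net_size, preset.net_size), lm_net,
                       HeatmapConfig(sigma=sigma), frame="net")
    return x, np.moveaxis(label.values, -1, 0)


def build_training_arrays(n_scenes: int, copies: int, preset: Preset,
                          sigma_ref: float, seed: int,
                          augment: bool = True
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """Augmented (X, Y) training arrays from ``n_scenes`` synthetic scenes."""
    sigma = scaled_sigma(sigma_ref, preset.net_size)
    xs, ys = [], []
    for i in range(n_scenes):
        scene = generate_scene(sample_scene_params(
            preset, seed=child_seed(seed, _TRAIN_NS + i)))
        base = ground_truth_window(scene, preset)
        if augment:
            spec = AugmentSpec(seed=child_seed(seed, _TRAIN_NS + i) ^ 0x5A5A)
            for c in range(copies):
                crop, lm_crop, _, _ = augment_once(
                    scene.image, scene.landmarks, base, spec, draw_index=c)
                x, y = _net_pair(crop, lm_crop, preset, sigma)
                xs.append(x)
                ys.append(y)
        else:
            from .roi import extract_crop
            crop = extract_crop(scene.image, base)
            x, y = _net_pair(crop, base.landmarks_to_crop(scene.landmarks),
                             preset, sigma)
            xs.append(x)
            ys.append(y)
    return np.stack(xs), np.stack(ys)


def build_validation_arrays(n_scenes: int, preset: Preset, sigma_ref: float,
                            seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """Un-augmented validation arrays (original crops, as in the protocol)."""
    from .roi import extract_crop
    sigma = scaled_sigma(sigma_ref, preset.net_size)
    xs, ys = [], []
    for i in range(n_scenes):
        scene = generate_scene(sample_scene_params(
            preset, seed=child_seed(seed, _VAL_NS + i)))
        base = ground_truth_window(scene, preset)
        crop = extract_crop(scene.image, base)
        x, y = _net_pair(crop, base.landmarks_to_crop(scene.landmarks),
                         preset, sigma)
        xs.append(x)
        ys.append(y)
    return np.stack(xs), np.stack(ys)


def build_test_scenes(n_scenes: int, preset: Preset, seed: int):
    return [generate_scene(sample_scene_params(
        preset, seed=child_seed(seed, _TEST_NS + i))) for i in range(n_scenes)]


def run_protocol(seed: int = 0, sigma_ref: float = 20.0,
                 preset: Optional[Preset] = None,
                 n_train_scenes: int = 50, copies: int = 4,
                 n_val_scenes: int = 8, n_test_scenes: int = 20,
                 epochs: int = 30, width_multiplier: float = 0.25,
                 detector=None) -> Dict:
    """Train the network on synthetic scenes and evaluate the full pipeline.

    Returns the trained model, loss history, per-image results and the
    summary, with errors both in crop-frame pixels and net pixels
    (crop error divided by the crop/net scale of 2.5).
    """
    preset = preset or TINY
    Xt, Yt = build_training_arrays(n_train_scenes, copies, preset, sigma_ref, seed)
    Xv, Yv = build_validation_arrays(n_val_scenes, preset, sigma_ref, seed)
    fcn_cfg = FCNConfig(net_size=preset.net_size,
                        width_multiplier=width_multiplier, seed=seed)
    model, history = train_fcn((Xt, Yt), (Xv, Yv),
                               TrainConfig(epochs=epochs, seed=seed),
                               fcn_config=fcn_cfg)
    scenes = build_test_scenes(n_test_scenes, preset, seed)
    detector = detector or OtsuSkullDetector()
    results, summary = evaluate_pipeline(scenes, detector, model, preset)
    scale = preset.crop_size / preset.net_size
    for name in ("bregma", "lambda"):
        summary[f"{name}_mean_error_netpx"] = summary[f"{name}_mean_error_px"] / scale
        summary[f"{name}_max_error_netpx"] = summary[f"{name}_max_error_px"] / scale
    return {"model": model, "history": history, "results": results,
            "summary": summary, "preset": preset, "sigma_ref": sigma_ref}
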