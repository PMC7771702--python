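"""Stage one: find the skull, cut the fixed-size crop.

The raw photograph is downsampled 4x, a detector proposes the skull
bounding box in the low-resolution frame, the box is mapped back to full
resolution, and a fixed 640 x 640 crop centred on it is extracted and
downsampled to the 256 x 256 network input.

The detector is pluggable: anything with a ``detect(lowres_image) ->
RoiDetection`` method works, so an external region-proposal network can
be slotted in.  Two implementations are bundled:

* :class:`OtsuSkullDetector` — deterministic rule-based baseline
  (smooth, Otsu-threshold, largest connected component); on well-lit
  scenes this is an exact, training-free oracle.
* :class:`RegressorDetector` — a small convolutional regressor trained
  on annotated low-resolution images, predicting the box centre and
  log-size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.transform import downscale_local_mean, resize

from . import nn
from .errors import DetectionError, InvalidInputError
from .frames import CropWindow, compute_crop_window, lowres_bbox_to_full

Bbox = Tuple[float, float, float, float]


@dataclass(frozen=True)
class RoiDetection:
    """One skull detection in the low-resolution frame."""

    bbox_lowres: Bbox
    score: float
    detector_id: str

    def __post_init__(self):
        r0, c0, r1, c1 = self.bbox_lowres
        if not (r0 < r1 and c0 < c1):
            raise InvalidInputError(f"degenerate detection bbox {self.bbox_lowres!r}")
        if not (0.0 <= self.score <= 1.0):
            raise InvalidInputError(f"score must be in [0, 1], got {self.score}")


def downsample(image: np.ndarray, factor: int = 4) -> np.ndarray:
    """Area-weighted (mean-preserving) integer downsampling.

    2448 x 3264 x 3 -> 612 x 816 x 3 at the default factor.  Images with
    dimensions not divisible by the factor are edge-padded up first.
    """
    if factor < 1:
        raise InvalidInputError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return image.copy()
    img = np.asarray(image)
    H, W = img.shape[:2]
    pad_r = (-H) % factor
    pad_c = (-W) % factor
    if pad_r or pad_c:
        pads = ((0, pad_r), (0, pad_c)) + (((0, 0),) if img.ndim == 3 else ())
        img = np.pad(img, pads, mode="edge")
    factors = (factor, factor) + ((1,) if img.ndim == 3 else ())
    out = downscale_local_mean(img.astype(np.float32), factors)
    return out.astype(np.float32)


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float32)
    return img.mean(axis=2) if img.ndim == 3 else img


class OtsuSkullDetector:
    """Rule-based baseline: the skull is the large bright blob.

    Smooth the grayscale image, threshold at the Otsu level, keep the
    largest connected foreground component.  The score is the rescaled
    foreground/background contrast; below ``min_score`` (e.g. on pure
    noise, where Otsu splits the noise distribution in half) detection
    is refused.
    """

    detector_id = "otsu-baseline"

    def __init__(self, smooth_sigma: float = 2.0, min_score: float = 0.12,
                 min_area_frac: float = 0.003, max_area_frac: float = 0.6):
        self.smooth_sigma = smooth_sigma
        self.min_score = min_score
        self.min_area_frac = min_area_frac
        self.max_area_frac = max_area_frac

    def detect(self, lowres_image: np.ndarray) -> RoiDetection:
        gray = _to_gray(lowres_image)
        smooth = ndi.gaussian_filter(gray, self.smooth_sigma)
        t = threshold_otsu(smooth)
        mask = smooth > t
        contrast = float(smooth[mask].mean() - smooth[~mask].mean()) / 255.0 if (
            mask.any() and not mask.all()) else 0.0
        score = float(np.clip(contrast, 0.0, 1.0))
        if score < self.min_score:
            raise DetectionError(
                f"no skull-like region: foreground/background contrast {score:.3f} "
                f"below {self.min_score} (Otsu level {t:.1f})")
        labels, n = ndi.label(mask)
        if n == 0:
            raise DetectionError("empty foreground after thresholding")
        sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
        best = int(np.argmax(sizes)) + 1
        frac = float(sizes[best - 1]) / mask.size
        if not (self.min_area_frac <= frac <= self.max_area_frac):
            raise DetectionError(
                f"largest component covers {frac:.4f} of the frame, outside "
                f"[{self.min_area_frac}, {self.max_area_frac}]")
        rows, cols = np.nonzero(labels == best)
        bbox = (float(rows.min()), float(cols.min()),
                float(rows.max() + 1), float(cols.max() + 1))
        return RoiDetection(bbox_lowres=bbox, score=score,
                            detector_id=self.detector_id)


def detect_skull(lowres_image: np.ndarray, detector) -> RoiDetection:
    """Run a detector and validate its output against the image bounds."""
    det = detector.detect(lowres_image)
    H, W = np.asarray(lowres_image).shape[:2]
    r0, c0, r1, c1 = det.bbox_lowres
    if r0 < 0 or c0 < 0 or r1 > H or c1 > W:
        raise DetectionError(f"detection {det.bbox_lowres!r} outside image {H}x{W}")
    return det


# ---- trainable bbox regressor -----------------------------------------

@dataclass(frozen=True)
class RegressorConfig:
    reg_input: int = 96          # square grayscale input fed to the net
    channels: Tuple[int, int, int, int] = (16, 32, 48, 64)
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 2e-3
    jitter_copies: int = 12      # jittered passes over the data per epoch
    lr_decay_epoch: int = 15     # drop the learning rate for the final epochs
    lr_decay_factor: float = 0.15
    tta: bool = True             # average predictions over the 4 flip variants


def _build_regressor_net(cfg: RegressorConfig, rng: np.random.Generator):
    # flatten (not pool) before the head: box regression needs location.
    # No batch norm: inputs are already per-image standardised, and norm
    # layers measurably slow position regression at this batch size.
    c1, c2, c3, c4 = cfg.channels
    feat = cfg.reg_input // 16
    return nn.Sequential([
        nn.Conv2d(1, c1, k=3, stride=2, rng=rng), nn.ReLU(),
        nn.Conv2d(c1, c2, k=3, stride=2, rng=rng), nn.ReLU(),
        nn.Conv2d(c2, c3, k=3, stride=2, rng=rng), nn.ReLU(),
        nn.Conv2d(c3, c4, k=3, stride=2, rng=rng), nn.ReLU(),
        nn.Flatten(),
        nn.Linear(c4 * feat * feat, 4, rng=rng),
    ])


class RegressorDetector:
    """Convolutional skull-box regressor (centre + log-size).

    Trained and applied at a single low-resolution image size; feeding a
    different size is an error rather than a silent rescale.
    """

    detector_id = "conv-regressor"

    def __init__(self, config: RegressorConfig, input_hw: Tuple[int, int],
                 seed: int = 0):
        self.config = config
        self.input_hw = tuple(int(v) for v in input_hw)
        self.seed = int(seed)
        self.net = _build_regressor_net(config, np.random.default_rng(seed))
        # whitening statistics of the regression targets, set by training
        self.target_mean = np.zeros(4, dtype=np.float32)
        self.target_std = np.ones(4, dtype=np.float32)
        self.trained = False

    # -- feature/target encoding
    def _encode_image(self, lowres_image: np.ndarray) -> np.ndarray:
        gray = _to_gray(lowres_image)
        s = self.config.reg_input
        small = resize(gray, (s, s), order=1, anti_aliasing=True,
                       preserve_range=True).astype(np.float32)
        # per-image standardisation: robust to the lighting ramp
        small = (small - small.mean()) / (small.std() + 1e-6)
        return small[None, :, :]

    def _encode_bbox(self, bbox: Bbox) -> np.ndarray:
        H, W = self.input_hw
        r0, c0, r1, c1 = bbox
        return np.array([
            (r0 + r1) / 2.0 / H, (c0 + c1) / 2.0 / W,
            np.log((r1 - r0) / H), np.log((c1 - c0) / W),
        ], dtype=np.float32)

    def _decode_bbox(self, t: np.ndarray) -> Bbox:
        H, W = self.input_hw
        cr, cc = t[0] * H, t[1] * W
        h, w = np.exp(t[2]) * H, np.exp(t[3]) * W
        r0 = float(np.clip(cr - h / 2, 0, H - 2))
        c0 = float(np.clip(cc - w / 2, 0, W - 2))
        r1 = float(np.clip(cr + h / 2, r0 + 1, H))
        c1 = float(np.clip(cc + w / 2, c0 + 1, W))
        return (r0, c0, r1, c1)

    def detect(self, lowres_image: np.ndarray) -> RoiDetection:
        if not self.trained:
            raise DetectionError("regressor has not been trained")
        if tuple(np.asarray(lowres_image).shape[:2]) != self.input_hw:
            raise InvalidInputError(
                f"regressor trained at {self.input_hw}, got "
                f"{np.asarray(lowres_image).shape[:2]}")
        x = self._encode_image(lowres_image)
        variants = [(False, False)]
        if self.config.tta:
            variants = [(fh, fv) for fh in (False, True) for fv in (False, True)]
        preds = []
        for fh, fv in variants:
            xx = x
            if fh:
                xx = xx[:, :, ::-1]
            if fv:
                xx = xx[:, ::-1, :]
            t = self.net.forward(np.ascontiguousarray(xx)[None], train=False)[0]
            t = t * self.target_std + self.target_mean
            if fh:
                t[1] = 1.0 - t[1]
            if fv:
                t[0] = 1.0 - t[0]
            preds.append(t)
        pred = np.mean(preds, axis=0)
        return RoiDetection(bbox_lowres=self._decode_bbox(pred), score=1.0,
                            detector_id=self.detector_id)


def _augment_encoded(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                     max_shift_frac: float = 0.15) -> Tuple[np.ndarray, np.ndarray]:
    """Box-consistent shift/flip jitter of one encoded (image, target) pair.

    Without this the regressor memorises the few training scenes instead
    of learning a translation-covariant notion of 'the bright blob'.
    """
    s = x.shape[-1]
    m = int(round(max_shift_frac * s))
    sr, sc = int(rng.integers(-m, m + 1)), int(rng.integers(-m, m + 1))
    out = ndi.shift(x, (0, sr, sc), order=0, mode="nearest")
    y = y.copy()
    y[0] += sr / s
    y[1] += sc / s
    if rng.random() < 0.5:
        out = out[:, :, ::-1]
        y[1] = 1.0 - y[1]
    if rng.random() < 0.5:
        out = out[:, ::-1, :]
        y[0] = 1.0 - y[0]
    return np.ascontiguousarray(out), y


def train_bbox_regressor(samples: Sequence[Tuple[np.ndarray, Bbox]],
                         config: Optional[RegressorConfig] = None,
                         seed: int = 0) -> RegressorDetector:
    """Fit the convolutional box regressor on (lowres image, lowres bbox) pairs.

    Training applies box-consistent shift/flip jitter each step.
    Deterministic given the seed: initialisation, shuffling, jitter and
    the optimiser all derive from it.
    """
    if len(samples) == 0:
        raise InvalidInputError("empty training set")
    config = config or RegressorConfig()
    input_hw = tuple(np.asarray(samples[0][0]).shape[:2])
    det = RegressorDetector(config, input_hw, seed=seed)
    X = np.stack([det._encode_image(img) for img, _ in samples])
    Y = np.stack([det._encode_bbox(bb) for _, bb in samples])
    # whitened targets: equalises the gradient weight of centre and size
    det.target_mean = Y.mean(axis=0).astype(np.float32)
    det.target_std = (Y.std(axis=0) + 1e-6).astype(np.float32)
    opt = nn.Adam(det.net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    n = len(samples)
    for epoch in range(config.epochs):
        if epoch == config.lr_decay_epoch:
            opt.lr = config.learning_rate * config.lr_decay_factor
        order = rng.permutation(np.repeat(np.arange(n), config.jitter_copies))
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = zip(*(_augment_encoded(X[i], Y[i], rng) for i in idx))
            opt.zero_grad()
            pred = det.net.forward(np.stack(xb), train=True)
            target = (np.stack(yb) - det.target_mean) / det.target_std
            _, grad = nn.mse_loss(pred, target)
            det.net.backward(grad)
            opt.step()
    det.trained = True
    return det


def save_detector(path, det: RegressorDetector) -> None:
    """Single-file checkpoint: weights, whitening stats, config echo, seed."""
    import json
    from dataclasses import asdict
    meta = {"config": asdict(det.config), "input_hw": list(det.input_hw),
            "seed": det.seed}
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(nn.get_state([det.net]))}
    np.savez(path, meta=json.dumps(meta), target_mean=det.target_mean,
             target_std=det.target_std, **arrays)


def load_detector(path) -> RegressorDetector:
    import json
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg = meta["config"]
    cfg["channels"] = tuple(cfg["channels"])
    det = RegressorDetector(RegressorConfig(**cfg), tuple(meta["input_hw"]),
                            seed=meta["seed"])
    keys = sorted(k for k in data.files if k.startswith("arr_"))
    nn.set_state([det.net], [data[k] for k in keys])
    det.target_mean = data["target_mean"]
    det.target_std = data["target_std"]
    det.trained = True
    return det


# ---- crop extraction ---------------------------------------------------

def extract_crop(full_image: np.ndarray, window: CropWindow) -> np.ndarray:
    """Cut the crop window out of the full image, edge-padding if needed."""
    img = np.asarray(full_image)
    H, W = img.shape[:2]
    S = window.crop_size
    r0, c0 = int(round(window.origin[0])), int(round(window.origin[1]))
    rs, re = max(r0, 0), min(r0 + S, H)
    cs, ce = max(c0, 0), min(c0 + S, W)
    if rs >= re or cs >= ce:
        raise InvalidInputError("crop window does not intersect the image")
    patch = img[rs:re, cs:ce]
    pads = ((rs - r0, r0 + S - re), (cs - c0, c0 + S - ce))
    if img.ndim == 3:
        pads = pads + ((0, 0),)
    if any(p for pair in pads for p in pair):
        patch = np.pad(patch, pads, mode="edge")
    return patch


def crop_to_net(crop: np.ndarray, net_size: int) -> np.ndarray:
    """Downsample a crop to the network input size, scaled to [0, 1]."""
    out = resize(crop.astype(np.float32), (net_size, net_size),
                 order=1, anti_aliasing=True, preserve_range=True)
    return (out / 255.0).astype(np.float32)


def extract_net_input(full_image: np.ndarray, detection: RoiDetection,
                      factor: int = 4, crop_size: int = 640,
                      net_size: int = 256) -> Tuple[np.ndarray, CropWindow]:
    """Full pipeline step: detection -> full-frame bbox -> crop -> net input.

    Returns the ``net_size`` x ``net_size`` x 3 float32 image in [0, 1]
    together with the :class:`CropWindow` needed to map predictions
    back to full-resolution coordinates.
    """
    bbox_full = lowres_bbox_to_full(detection.bbox_lowres, factor)
    window = compute_crop_window(bbox_full, np.asarray(full_image).shape[:2],
                                 crop_size=crop_size, net_size=net_size)
    crop = extract_crop(full_image, window)
    return crop_to_net(crop, net_size), window


def bbox_iou(a: Bbox, b: Bbox) -> float:
    """Intersection-over-union of two (row0, col0, row1, col1) boxes."""
    r0, c0 = max(a[0], b[0]), max(a[1], b[1])
    r1, c1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0.0, r1 - r0) * max(0.0, c1 - c0)
    area = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return inter / area if area > 0 else 0.0
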