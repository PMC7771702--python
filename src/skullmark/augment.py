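"""Label-consistent augmentation and the cross-validation layout.

Each training crop is augmented by shifting the crop window inside the
full image, rotating the cropped content about the crop centre and
randomly flipping it.  Landmark coordinates are pushed through the same
analytic transform and the Gaussian labels are *regenerated* in the
augmented frame — never pixel-resampled — so the supervision carries no
interpolation bias.  The published protocol makes 100 augmented copies
of each training image (80 originals -> 8000 items) and evaluates with
4-fold cross-validation: five subsets, a fixed 13-image test subset,
and a 20-image validation subset rotating over the remaining four.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .errors import AugmentationError, SplitError
from .frames import CropWindow, LandmarkSet
from .roi import extract_crop
from .synthetic import child_seed


@dataclass(frozen=True)
class AugmentSpec:
    """Random draw distribution for one augmentation."""

    p_flip_h: float = 0.5
    p_flip_v: float = 0.5
    rotation_range: Tuple[float, float] = (0.0, 360.0)
    shift_frac: float = 0.10          # window shift, fraction of crop size
    copies_per_image: int = 100
    seed: int = 0
    max_retries: int = 25
    mode: str = "window"              # "window": shift the crop window in the
                                      # full image; "pixel": translate pixels
                                      # inside a fixed crop (fallback)


@dataclass(frozen=True)
class AugmentDraw:
    flip_h: bool
    flip_v: bool
    angle_deg: float
    shift: Tuple[float, float]        # (row, col) in full-frame pixels


def sample_draw(spec: AugmentSpec, rng: np.random.Generator) -> AugmentDraw:
    S = None  # shift is scaled by the caller's crop size
    return AugmentDraw(
        flip_h=bool(rng.random() < spec.p_flip_h),
        flip_v=bool(rng.random() < spec.p_flip_v),
        angle_deg=float(rng.uniform(*spec.rotation_range)),
        shift=(float(rng.uniform(-spec.shift_frac, spec.shift_frac)),
               float(rng.uniform(-spec.shift_frac, spec.shift_frac))),
    )


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def transform_point(p, draw: AugmentDraw, crop_size: int) -> np.ndarray:
    """Apply the draw's rotation-then-flips to a crop-frame point."""
    S = crop_size
    centre = np.array([(S - 1) / 2.0, (S - 1) / 2.0])
    q = _rotation_matrix(draw.angle_deg) @ (np.asarray(p, float) - centre) + centre
    if draw.flip_v:
        q[0] = S - 1 - q[0]
    if draw.flip_h:
        q[1] = S - 1 - q[1]
    return q


def _transform_image(crop: np.ndarray, draw: AugmentDraw) -> np.ndarray:
    """Same map as :func:`transform_point`, applied to the pixels."""
    S = crop.shape[0]
    centre = np.array([(S - 1) / 2.0, (S - 1) / 2.0])
    # output[o] = input[A @ o + offset] with A the inverse rotation
    A = _rotation_matrix(-draw.angle_deg)
    offset = centre - A @ centre
    img = crop.astype(np.float32)
    if img.ndim == 3:
        out = np.stack([ndi.affine_transform(img[:, :, ch], A, offset=offset,
                                             order=1, mode="nearest")
                        for ch in range(img.shape[2])], axis=-1)
    else:
        out = ndi.affine_transform(img, A, offset=offset, order=1, mode="nearest")
    if draw.flip_v:
        out = out[::-1]
    if draw.flip_h:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def _clamp_origin(origin, image_shape, crop_size) -> Tuple[float, float]:
    out = []
    for o, size in zip(origin, image_shape):
        if size >= crop_size:
            o = min(max(o, 0.0), size - crop_size)
        else:
            o = (size - crop_size) / 2.0
        out.append(float(np.floor(o + 0.5)))
    return tuple(out)


def augment_once(full_image: np.ndarray, landmarks: LandmarkSet,
                 base_window: CropWindow, spec: AugmentSpec, draw_index: int,
                 draw: Optional[AugmentDraw] = None,
                 ) -> Tuple[np.ndarray, LandmarkSet, CropWindow, AugmentDraw]:
    """One augmented (crop image, crop-frame landmarks) pair.

    Draws are retried (up to ``spec.max_retries``) until both landmarks
    stay inside the crop; the accepted draw is returned so it can be
    logged.  Supplying ``draw`` skips sampling (used by tests).
    """
    if landmarks.frame != "full":
        raise AugmentationError("augment_once expects full-frame landmarks")
    H, W = np.asarray(full_image).shape[:2]
    S = base_window.crop_size
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, draw_index]))
    draws = [draw] if draw is not None else (
        sample_draw(spec, rng) for _ in range(spec.max_retries))

    for d in draws:
        if spec.mode == "window":
            shift_px = (d.shift[0] * S, d.shift[1] * S)
            origin = _clamp_origin(
                (base_window.origin[0] + shift_px[0],
                 base_window.origin[1] + shift_px[1]), (H, W), S)
            window = CropWindow(origin=origin, crop_size=S,
                                net_size=base_window.net_size)
        else:  # pixel mode: fixed window, content translated via the draw
            window = base_window
        lm_crop = np.array([window.full_to_crop(landmarks.bregma),
                            window.full_to_crop(landmarks.lambda_)])
        if spec.mode == "pixel":
            lm_crop = lm_crop - np.array(d.shift)[None, :] * S
        pts = [transform_point(p, d, S) for p in lm_crop]
        if all(0 <= p[0] <= S - 1 and 0 <= p[1] <= S - 1 for p in pts):
            crop = extract_crop(full_image, window)
            if spec.mode == "pixel":
                crop = ndi.shift(crop.astype(np.float32),
                                 (d.shift[0] * S, d.shift[1] * S) + (0,) * (crop.ndim - 2),
                                 order=1, mode="nearest")
            out = _transform_image(crop, d)
            lm_out = LandmarkSet(bregma=tuple(pts[0]), lambda_=tuple(pts[1]),
                                 frame="crop")
            return out, lm_out, window, d
    raise AugmentationError(
        f"draw {draw_index}: landmarks expelled from the crop in "
        f"{spec.max_retries} attempts")


def expand_dataset(train_images: Sequence, spec: AugmentSpec) -> pd.DataFrame:
    """Augmentation plan: one row per (image, copy) with its derived seed.

    The plan is lazy bookkeeping — materialisation happens per row via
    :func:`augment_once` — so counting and splitting stay cheap.
    Output size is exactly ``len(train_images) * copies_per_image``.
    """
    if spec.copies_per_image < 1:
        raise AugmentationError("copies_per_image must be >= 1")
    rows = []
    for i, image_id in enumerate(train_images):
        for c in range(spec.copies_per_image):
            rows.append({
                "image_id": image_id,
                "copy": c,
                "draw_seed": child_seed(spec.seed, i * spec.copies_per_image + c),
            })
    return pd.DataFrame(rows, columns=["image_id", "copy", "draw_seed"])


def write_augmentation_log(path, records: Sequence[dict]) -> None:
    """CSV log of accepted draws: one row per (image, copy) with its
    flip/angle/shift values and derived seed."""
    pd.DataFrame(records, columns=["image_id", "copy", "draw_seed", "flip_h",
                                   "flip_v", "angle_deg", "shift_row",
                                   "shift_col"]).to_csv(path, index=False)


def draw_record(image_id, copy: int, draw_seed: int, draw: AugmentDraw) -> dict:
    return {"image_id": image_id, "copy": copy, "draw_seed": draw_seed,
            "flip_h": draw.flip_h, "flip_v": draw.flip_v,
            "angle_deg": draw.angle_deg,
            "shift_row": draw.shift[0], "shift_col": draw.shift[1]}


# ---- cross-validation layout ------------------------------------------

@dataclass(frozen=True)
class CvLayout:
    """Five subsets; subset 5 is the fixed test set, validation rotates."""

    n_subsets: int = 5
    folds: int = 4
    test_fraction: float = 13.0 / 93.0   # published proportion (13 of 93)


@dataclass(frozen=True)
class FoldPlan:
    subsets: Tuple[Tuple[str, ...], ...]   # n_subsets tuples of image ids
    folds: Tuple[Dict[str, Tuple[str, ...]], ...]

    def manifest(self) -> pd.DataFrame:
        rows = []
        for f, fold in enumerate(self.folds):
            for role in ("train", "val", "test"):
                for image_id in fold[role]:
                    rows.append({"fold": f + 1, "image_id": image_id, "role": role})
        return pd.DataFrame(rows, columns=["fold", "image_id", "role"])


def make_cv_folds(annotations: pd.DataFrame, layout: Optional[CvLayout] = None,
                  seed: int = 0) -> FoldPlan:
    """Deterministic subset assignment and the rotating-validation folds.

    With 93 images and the default layout this reproduces the published
    composition: four 20-image subsets, a 13-image test subset, and per
    fold 60 training originals / 20 validation originals / 13 test.
    """
    layout = layout or CvLayout()
    ids = list(annotations["image_id"])
    n = len(ids)
    if n < layout.n_subsets:
        raise SplitError(f"need at least {layout.n_subsets} images, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    order = [ids[i] for i in rng.permutation(n)]

    n_test = max(1, int(round(n * layout.test_fraction)))
    n_rot = layout.n_subsets - 1
    base, extra = divmod(n - n_test, n_rot)
    if base < 1:
        raise SplitError(f"too few images ({n}) for {n_rot} rotating subsets")
    subsets: List[Tuple[str, ...]] = []
    pos = 0
    for s in range(n_rot):
        k = base + (1 if s < extra else 0)
        subsets.append(tuple(order[pos:pos + k]))
        pos += k
    subsets.append(tuple(order[pos:]))  # test subset
    assert len(subsets[-1]) == n_test

    folds = []
    for f in range(layout.folds):
        val = subsets[f]
        train = tuple(i for s in range(n_rot) if s != f for i in subsets[s])
        folds.append({"train": train, "val": val, "test": subsets[-1]})
    return FoldPlan(subsets=tuple(subsets), folds=tuple(folds))


def write_fold_manifest(path, plan: FoldPlan) -> None:
    doc = {
        "n_subsets": len(plan.subsets),
        "subsets": [list(s) for s in plan.subsets],
        "folds": [{k: list(v) for k, v in fold.items()} for fold in plan.folds],
    }
    with open(Path(path), "w") as fh:
        yaml.safe_dump(doc, fh)
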