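"""Seeded generator of skull-like photographs with exact ground truth.

Real data for this problem are overhead photographs of a rodent skull:
a bright, roughly elliptical bone surface on a darker background, a dark
sagittal (midline) suture running tail-to-head, a coronal suture whose
midline crossing is **bregma** and a lambdoid suture whose crossing is
**lambda**, under uncontrolled lighting and arbitrary orientation.

The generator is parametric-geometry-first: landmark coordinates and
bounding boxes are computed analytically from the curve parameters and
the pixels are rendered afterwards, so the ground truth is exact by
construction and never read back from the image.  The coronal suture is
drawn nearly transverse (a shallow-angled arc) while the lambdoid is a
steep chevron with its apex at lambda, which makes the two crossings
visually distinguishable at any orientation — as they are on real
skulls.  Dark vessel-like distractor curves can be placed parallel to
the midline, mimicking the blood vessels that are the main confuser in
photographs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize

from .errors import ConfigError, InvalidInputError, SplitError
from .frames import LandmarkSet

ANNOTATION_COLUMNS = [
    "image_id", "image_path", "split",
    "bbox_row0", "bbox_col0", "bbox_row1", "bbox_col1",
    "bregma_row", "bregma_col", "lambda_row", "lambda_col",
]


@dataclass(frozen=True)
class Preset:
    """Resolution regime for a whole experiment.

    ``full`` matches the photographic setup all pipeline constants were
    written for (2448 x 3264 canvas, factor-4 lowres, 640-crop, 256-net);
    ``tiny`` is a 4x-reduced replica (612 x 816 canvas, 160-crop, 64-net)
    used for fast CPU experiments.  Crop/net scale is 2.5 in both.
    """

    name: str
    image_shape: Tuple[int, int]
    downsample_factor: int
    crop_size: int
    net_size: int
    skull_a_range: Tuple[float, float]   # semi-axis along the midline, px
    skull_b_range: Tuple[float, float]   # transverse semi-axis, px
    distance_range: Tuple[float, float]  # bregma-lambda distance, px


FULL = Preset(
    name="full", image_shape=(2448, 3264), downsample_factor=4,
    crop_size=640, net_size=256,
    skull_a_range=(260.0, 330.0), skull_b_range=(190.0, 240.0),
    distance_range=(140.0, 190.0),  # centred near the observed 163 px
)

TINY = Preset(
    name="tiny", image_shape=(612, 816), downsample_factor=4,
    crop_size=160, net_size=64,
    skull_a_range=(65.0, 82.5), skull_b_range=(47.5, 60.0),
    distance_range=(35.0, 47.5),
)

PRESETS = {"full": FULL, "tiny": TINY}

# suture geometry (angles from the transverse direction, toward anterior)
CORONAL_SWEEP_DEG = 15.0
LAMBDOID_SWEEP_DEG = 48.0


@dataclass(frozen=True)
class SkullSceneParams:
    """Concrete sampled parameters of one scene (all lengths in px)."""

    image_shape: Tuple[int, int]
    skull_center: Tuple[float, float]
    skull_axes: Tuple[float, float]          # (a along midline, b transverse)
    orientation_deg: float                   # anterior direction angle
    bregma_lambda_distance: float
    lighting_angle_deg: float
    lighting_strength: float                 # relative ramp amplitude
    noise_sd: float
    vessel_count: int
    vessel_offsets: Tuple[float, ...]        # lateral offsets, fraction of b
    skull_taper: float = 0.25                # anterior narrowing (egg shape)
    skull_level: float = 178.0
    background_level: float = 66.0
    suture_depth: float = 60.0               # darkness of suture lines
    suture_width: float = 3.0
    seed: int = 0

    def anterior_axis(self) -> np.ndarray:
        a = np.deg2rad(self.orientation_deg)
        return np.array([np.cos(a), np.sin(a)])  # (row, col) unit vector

    def transverse_axis(self) -> np.ndarray:
        a = np.deg2rad(self.orientation_deg)
        return np.array([-np.sin(a), np.cos(a)])


@dataclass(frozen=True)
class AnnotatedImage:
    image: np.ndarray                 # (H, W, 3) uint8
    bbox: Tuple[float, float, float, float]
    landmarks: LandmarkSet            # full frame
    params: SkullSceneParams


def _scene_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-scene seed (counter scheme; datasets are extensible)."""
    h = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def sample_scene_params(preset: Preset = FULL, seed: int = 0) -> SkullSceneParams:
    """Draw one scene's parameters; everything reproducible from ``seed``."""
    rng = _scene_rng(seed, 0)
    H, W = preset.image_shape
    a = rng.uniform(*preset.skull_a_range)
    b = rng.uniform(*preset.skull_b_range)
    orientation = rng.uniform(0.0, 360.0)
    d = rng.uniform(*preset.distance_range)
    # keep the tight outline bbox inside the canvas (1.25: egg-taper widening)
    ang = np.deg2rad(orientation)
    b_eff = 1.25 * b
    ext_r = np.hypot(a * np.cos(ang), b_eff * np.sin(ang))
    ext_c = np.hypot(a * np.sin(ang), b_eff * np.cos(ang))
    margin = 6.0
    cr = rng.uniform(ext_r + margin, H - ext_r - margin)
    cc = rng.uniform(ext_c + margin, W - ext_c - margin)
    n_vessels = int(rng.integers(1, 4))
    offsets = tuple(float(s * rng.uniform(0.12, 0.4))
                    for s in rng.choice([-1.0, 1.0], size=n_vessels))
    return SkullSceneParams(
        image_shape=(H, W),
        skull_center=(float(cr), float(cc)),
        skull_axes=(float(a), float(b)),
        orientation_deg=float(orientation),
        bregma_lambda_distance=float(d),
        lighting_angle_deg=float(rng.uniform(0.0, 360.0)),
        lighting_strength=float(rng.uniform(0.05, 0.25)),
        noise_sd=6.0,
        vessel_count=n_vessels,
        vessel_offsets=offsets,
        # width is constant in crop pixels: the crop/net ratio is 2.5 in every
        # preset, so this keeps sutures equally visible at net resolution
        suture_width=3.0,
        seed=int(seed),
    )


# ---- analytic annotation ----------------------------------------------

def landmark_positions(params: SkullSceneParams) -> LandmarkSet:
    """Bregma/lambda from the curve parameters (never from pixels)."""
    c = np.asarray(params.skull_center)
    u = params.anterior_axis()
    half = params.bregma_lambda_distance / 2.0
    a = params.skull_axes[0]
    if half >= 0.92 * a:
        raise ConfigError("bregma-lambda distance does not fit inside the skull")
    bregma = c + half * u
    lam = c - half * u
    H, W = params.image_shape
    for p in (bregma, lam):
        if not (0 <= p[0] < H and 0 <= p[1] < W):
            raise ConfigError("landmark falls outside the image")
    return LandmarkSet(bregma=tuple(bregma), lambda_=tuple(lam), frame="full")


def skull_outline(params: SkullSceneParams, n_points: int = 2048) -> np.ndarray:
    """Boundary points of the tapered (egg-shaped) skull outline.

    The outline is the ellipse ``center + a cos(t) u + b w(cos t) sin(t) v``
    with a lateral width factor ``w(t) = 1 - taper * t`` that narrows the
    anterior (snout) end, as on a real rodent cranium.
    """
    c = np.asarray(params.skull_center)
    u, v = params.anterior_axis(), params.transverse_axis()
    a, b = params.skull_axes
    t = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    ct, s = np.cos(t), np.sin(t)
    lat = b * (1.0 - params.skull_taper * ct) * s
    return c[None, :] + a * ct[:, None] * u[None, :] + lat[:, None] * v[None, :]


def skull_bbox(params: SkullSceneParams) -> Tuple[float, float, float, float]:
    """Tight axis-aligned box of the rendered skull outline."""
    pts = skull_outline(params)
    H, W = params.image_shape
    return (max(0.0, float(pts[:, 0].min())), max(0.0, float(pts[:, 1].min())),
            min(float(H), float(pts[:, 0].max())), min(float(W), float(pts[:, 1].max())))


def suture_segments(params: SkullSceneParams):
    """Endpoints of every suture segment, keyed by suture name.

    The midline runs through both landmarks; the coronal pair meets the
    midline exactly at bregma and the lambdoid pair exactly at lambda,
    so re-intersecting these curves recovers the annotation.
    """
    c = np.asarray(params.skull_center)
    u, v = params.anterior_axis(), params.transverse_axis()
    a, b = params.skull_axes
    lm = landmark_positions(params)
    bregma, lam = np.asarray(lm.bregma), np.asarray(lm.lambda_)

    sweep_c = np.deg2rad(CORONAL_SWEEP_DEG)
    sweep_l = np.deg2rad(LAMBDOID_SWEEP_DEG)
    segs = {"sagittal": [(c - 0.9 * a * u, c + 0.9 * a * u)]}
    segs["coronal"] = [
        (bregma, bregma + 0.8 * b * (s * np.cos(sweep_c) * v + np.sin(sweep_c) * u))
        for s in (-1.0, 1.0)
    ]
    segs["lambdoid"] = [
        (lam, lam + 0.7 * b * (s * np.cos(sweep_l) * v + np.sin(sweep_l) * u))
        for s in (-1.0, 1.0)
    ]
    return segs


def rederive_landmarks(params: SkullSceneParams) -> LandmarkSet:
    """Independent re-derivation: intersect each transverse suture with the midline.

    Solves the 2x2 linear system for the sagittal line against one
    coronal and one lambdoid segment; used to check self-consistency of
    the stored annotation.
    """
    segs = suture_segments(params)
    (p0, p1) = segs["sagittal"][0]

    def intersect(q0, q1):
        # p0 + t (p1-p0) = q0 + s (q1-q0)
        A = np.column_stack([p1 - p0, -(q1 - q0)])
        t, _ = np.linalg.solve(A, q0 - p0)
        return p0 + t * (p1 - p0)

    bregma = intersect(*segs["coronal"][0])
    lam = intersect(*segs["lambdoid"][0])
    return LandmarkSet(bregma=tuple(bregma), lambda_=tuple(lam), frame="full")


# ---- rendering ---------------------------------------------------------

def _segment_distance(rr, cc, p0, p1):
    """Distance of every grid point to the segment p0-p1 (vectorised)."""
    d = p1 - p0
    L2 = float(d @ d)
    wr, wc = rr - p0[0], cc - p0[1]
    t = np.clip((wr * d[0] + wc * d[1]) / L2, 0.0, 1.0)
    return np.hypot(wr - t * d[0], wc - t * d[1])


def render_scene(params: SkullSceneParams) -> np.ndarray:
    """Render the uint8 RGB image for a parameter set."""
    H, W = params.image_shape
    rng = _scene_rng(params.seed, 1)

    # textured background over the whole canvas
    coarse = rng.standard_normal((max(2, H // 64), max(2, W // 64)),
                                 dtype=np.float32)
    texture = resize(coarse, (H, W), order=1, mode="edge", anti_aliasing=False)
    img = np.full((H, W), params.background_level, dtype=np.float32)
    img += 12.0 * texture.astype(np.float32)

    # skull ellipse and sutures, evaluated on the bbox neighbourhood only
    r0, c0, r1, c1 = skull_bbox(params)
    m = int(3 * params.suture_width) + 6
    r0i, c0i = max(0, int(r0) - m), max(0, int(c0) - m)
    r1i, c1i = min(H, int(r1) + m), min(W, int(c1) + m)
    rr = np.arange(r0i, r1i, dtype=np.float32)[:, None]
    cc = np.arange(c0i, c1i, dtype=np.float32)[None, :]
    u, v = params.anterior_axis(), params.transverse_axis()
    a, b = params.skull_axes
    dr, dc = rr - params.skull_center[0], cc - params.skull_center[1]
    t_n = (dr * u[0] + dc * u[1]) / a          # axial coordinate, anterior > 0
    s_n = (dr * v[0] + dc * v[1]) / b
    width = 1.0 - params.skull_taper * np.clip(t_n, -1.5, 1.5)  # egg taper
    q = t_n**2 + (s_n / width) ** 2
    alpha = np.clip((1.0 - q) / 0.06, 0.0, 1.0)  # soft outline edge

    skull = params.skull_level + 22.0 * (1.0 - q)

    w = params.suture_width
    dark = np.zeros_like(q)
    for segs in suture_segments(params).values():
        for (p0, p1) in segs:
            dist = _segment_distance(rr, cc, p0, p1)
            dark = np.maximum(dark, np.clip(1.0 - dist / w, 0.0, 1.0))
    skull -= params.suture_depth * dark

    # vessel distractors parallel to the midline
    c = np.asarray(params.skull_center)
    lm = landmark_positions(params)
    for off in params.vessel_offsets:
        p0 = np.asarray(lm.lambda_) + off * b * v
        p1 = np.asarray(lm.bregma) + off * b * v + 0.15 * a * u
        dist = _segment_distance(rr, cc, p0, p1)
        skull -= 0.45 * params.suture_depth * np.clip(1.0 - dist / (0.6 * w), 0.0, 1.0)

    patch = img[r0i:r1i, c0i:c1i]
    img[r0i:r1i, c0i:c1i] = (1.0 - alpha) * patch + alpha * skull

    # linear lighting ramp across the canvas
    la = float(np.deg2rad(params.lighting_angle_deg))
    span = np.float32(params.lighting_strength / (0.5 * np.hypot(H, W)))
    gr = ((np.arange(H, dtype=np.float32) - H / 2) * np.float32(np.cos(la)))[:, None]
    gc = ((np.arange(W, dtype=np.float32) - W / 2) * np.float32(np.sin(la)))[None, :]
    img *= np.float32(1.0) + span * (gr + gc)

    img += params.noise_sd * rng.standard_normal((H, W), dtype=np.float32)

    np.clip(img, 0.0, 255.0, out=img)
    rgb = np.empty((H, W, 3), dtype=np.uint8)
    for ch, t in enumerate((1.0, 0.97, 0.92)):  # warm tint; t <= 1 keeps range
        rgb[:, :, ch] = (img * np.float32(t)).astype(np.uint8)
    return rgb


def generate_scene(params: Optional[SkullSceneParams] = None, *,
                   preset: Preset = FULL, seed: int = 0) -> AnnotatedImage:
    """Render one annotated scene (sampling parameters first if needed)."""
    if params is None:
        params = sample_scene_params(preset, seed=seed)
    landmarks = landmark_positions(params)
    return AnnotatedImage(
        image=render_scene(params),
        bbox=skull_bbox(params),
        landmarks=landmarks,
        params=params,
    )


# ---- datasets ----------------------------------------------------------

def _split_counts(n: int, split: Sequence[float]) -> Tuple[int, ...]:
    if abs(sum(split) - 1.0) > 1e-9:
        raise SplitError(f"split fractions must sum to 1, got {split!r}")
    nonzero = sum(1 for f in split if f > 0)
    if n < nonzero:
        raise SplitError(f"cannot split {n} items into {nonzero} non-empty subsets")
    counts = [int(np.floor(n * f)) for f in split]
    # largest-remainder top-up
    rema = sorted(range(len(split)), key=lambda i: n * split[i] - counts[i], reverse=True)
    for i in rema:
        if sum(counts) == n:
            break
        if split[i] > 0:
            counts[i] += 1
    return tuple(counts)


def generate_annotations(n: int, preset: Preset = FULL, seed: int = 0,
                         split: Sequence[float] = (1.0, 0.0, 0.0)) -> pd.DataFrame:
    """Annotation table for ``n`` scenes without rendering any pixels.

    Ground truth is analytic, so dataset-level bookkeeping (splits,
    cross-validation folds) never needs the images themselves.
    """
    counts = _split_counts(n, split)
    roles = [r for r, k in zip(("train", "val", "test"), counts) for _ in range(k)]
    rows = []
    for i in range(n):
        p = sample_scene_params(preset, seed=child_seed(seed, i))
        lm = landmark_positions(p)
        bb = skull_bbox(p)
        rows.append({
            "image_id": f"scene_{i:05d}",
            "image_path": f"scene_{i:05d}.png",
            "split": roles[i],
            "bbox_row0": bb[0], "bbox_col0": bb[1],
            "bbox_row1": bb[2], "bbox_col1": bb[3],
            "bregma_row": lm.bregma[0], "bregma_col": lm.bregma[1],
            "lambda_row": lm.lambda_[0], "lambda_col": lm.lambda_[1],
        })
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def generate_dataset(n: int, out_dir, split: Sequence[float] = (0.65, 0.21, 0.14),
                     seed: int = 0, preset: Preset = FULL) -> pd.DataFrame:
    """Render ``n`` scenes to PNG, write the annotation CSV and a manifest.

    Per-scene seeds come from a counter scheme on the master seed, so
    regenerating with a larger ``n`` extends the dataset without
    reshuffling existing scenes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = generate_annotations(n, preset=preset, seed=seed, split=split)
    for i, row in table.iterrows():
        params = sample_scene_params(preset, seed=child_seed(seed, i))
        iio.imwrite(out / row["image_path"], render_scene(params))
    table.to_csv(out / "annotations.csv", index=False)
    manifest = {
        "preset": preset.name,
        "seed": int(seed),
        "n": int(n),
        "split": [float(f) for f in split],
        "scene_seeds": [int(child_seed(seed, i)) for i in range(n)],
        "annotation_csv": "annotations.csv",
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return table


def read_annotations(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidInputError(f"annotation file missing columns {sorted(missing)}")
    return table


def landmarks_from_row(row) -> LandmarkSet:
    return LandmarkSet(
        bregma=(float(row["bregma_row"]), float(row["bregma_col"])),
        lambda_=(float(row["lambda_row"]), float(row["lambda_col"])),
        frame="full",
    )


def bbox_from_row(row) -> Tuple[float, float, float, float]:
    return (float(row["bbox_row0"]), float(row["bbox_col0"]),
            float(row["bbox_row1"]), float(row["bbox_col1"]))
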