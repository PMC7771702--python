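"""Gaussian heatmap labels and argmax decoding.

The stage-two network is trained as a regressor: each landmark is
represented by a truncated, un-normalised 2-D Gaussian bump centred on
the landmark, peak value 1, standard deviation ``sigma`` pixels (20 on
the reference 256 x 256 grid).  The predicted landmark is the coordinate
of the per-channel maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import tifffile

from .errors import ConfigError, FrameError, InvalidInputError
from .frames import LandmarkSet

#: reference net grid on which the default sigma of 20 px is defined
REFERENCE_NET_SIZE = 256


@dataclass(frozen=True)
class HeatmapConfig:
    """Shape of the Gaussian label bump.

    ``sigma`` is in pixels of the grid the label is written on; values
    farther than ``truncation_radius`` (default 3 sigma, >98.9% of the
    mass) from the centre are exactly zero, which keeps the label sparse
    and its support testable.
    """

    sigma: float = 20.0
    peak: float = 1.0
    truncation_radius: Optional[float] = None

    def __post_init__(self):
        if not (self.sigma > 0):
            raise ConfigError(f"sigma must be > 0, got {self.sigma}")
        if not (self.peak > 0):
            raise ConfigError(f"peak must be > 0, got {self.peak}")
        if self.truncation_radius is None:
            object.__setattr__(self, "truncation_radius", 3.0 * self.sigma)
        if self.truncation_radius < self.sigma:
            raise ConfigError("truncation_radius must be >= sigma")


def scaled_sigma(sigma_ref: float, net_size: int) -> float:
    """Scale a reference-frame sigma (defined on the 256 grid) to ``net_size``.

    Keeps the bump's extent relative to the skull unchanged when an
    experiment is run at a reduced working resolution.
    """
    return sigma_ref * net_size / REFERENCE_NET_SIZE


@dataclass(frozen=True)
class HeatmapLabel:
    """Two-channel label grid: channel 0 = bregma, channel 1 = lambda."""

    values: np.ndarray  # (H, W, 2) float32
    config: HeatmapConfig = field(default_factory=HeatmapConfig)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[2] != 2:
            raise InvalidInputError(f"label must be (H, W, 2), got {v.shape}")


def make_gaussian_heatmap(shape, center, config: HeatmapConfig) -> np.ndarray:
    """Single-channel truncated Gaussian bump.

    ``value(p) = peak * exp(-||p - center||^2 / (2 sigma^2))`` for
    ``||p - center|| <= truncation_radius``, else exactly 0.  Evaluated
    at integer pixel centres; the centre itself may be sub-pixel or lie
    outside the grid (only the in-grid tail is written).
    """
    H, W = int(shape[0]), int(shape[1])
    if H <= 0 or W <= 0:
        raise InvalidInputError(f"shape must be positive, got {shape!r}")
    cr, cc = float(center[0]), float(center[1])
    if not (np.isfinite(cr) and np.isfinite(cc)):
        raise InvalidInputError(f"center must be finite, got {center!r}")

    out = np.zeros((H, W), dtype=np.float32)
    rad = float(config.truncation_radius)
    # only evaluate the bounding square of the truncation disc
    r0, r1 = max(0, int(np.floor(cr - rad))), min(H, int(np.ceil(cr + rad)) + 1)
    c0, c1 = max(0, int(np.floor(cc - rad))), min(W, int(np.ceil(cc + rad)) + 1)
    if r0 >= r1 or c0 >= c1:
        return out
    rr = np.arange(r0, r1, dtype=np.float64)[:, None] - cr
    cc_ = np.arange(c0, c1, dtype=np.float64)[None, :] - cc
    d2 = rr * rr + cc_ * cc_
    patch = config.peak * np.exp(-d2 / (2.0 * config.sigma**2))
    patch[d2 > rad * rad] = 0.0
    out[r0:r1, c0:c1] = patch.astype(np.float32)
    return out


def make_label(shape, landmarks: LandmarkSet, config: HeatmapConfig,
               frame: Optional[str] = None) -> HeatmapLabel:
    """Build the two-channel label for a landmark pair.

    The channels are written independently (no cross-channel mixing even
    when the bumps overlap).  If ``frame`` is given it must match the
    landmark set's frame — a cheap guard against building labels from
    coordinates expressed on the wrong grid.
    """
    if frame is not None and landmarks.frame != frame:
        raise FrameError(
            f"landmarks are in frame {landmarks.frame!r}, label grid expects {frame!r}"
        )
    values = np.stack(
        [
            make_gaussian_heatmap(shape, landmarks.bregma, config),
            make_gaussian_heatmap(shape, landmarks.lambda_, config),
        ],
        axis=-1,
    )
    return HeatmapLabel(values=values, config=config)


def decode_heatmap(values: np.ndarray, frame: str = "net") -> LandmarkSet:
    """Per-channel argmax decoding.

    Ties are broken by the smallest row-major index, so a constant
    channel decodes to (0, 0) deterministically.
    """
    v = np.asarray(values)
    if v.ndim != 3 or v.shape[2] != 2 or v.shape[0] == 0 or v.shape[1] == 0:
        raise InvalidInputError(f"expected non-empty (H, W, 2) grid, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("heatmap contains non-finite values")
    coords = []
    for ch in range(2):
        idx = int(np.argmax(v[:, :, ch]))  # row-major, first max wins
        coords.append(tuple(float(x) for x in np.unravel_index(idx, v.shape[:2])))
    if coords[0] == coords[1]:
        return LandmarkSet.unchecked(coords[0], coords[1], frame)
    return LandmarkSet(bregma=coords[0], lambda_=coords[1], frame=frame)


# ---- persistence -------------------------------------------------------

def save_label_tiff(path, label: HeatmapLabel) -> None:
    """Persist a label as a 2-channel 32-bit TIFF."""
    tifffile.imwrite(str(path), np.moveaxis(label.values, -1, 0).astype(np.float32))


def load_label_tiff(path, config: Optional[HeatmapConfig] = None) -> HeatmapLabel:
    arr = tifffile.imread(str(path))
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise InvalidInputError(f"expected 2-channel TIFF, got shape {arr.shape}")
    return HeatmapLabel(values=np.moveaxis(arr, 0, -1),
                        config=config or HeatmapConfig())


def label_preview_rgb(label: HeatmapLabel) -> np.ndarray:
    """uint8 RGB preview: bregma red, lambda green, blue channel all zero."""
    v = np.clip(label.values / label.config.peak, 0.0, 1.0)
    rgb = np.zeros((*v.shape[:2], 3), dtype=np.uint8)
    rgb[:, :, 0] = (v[:, :, 0] * 255).astype(np.uint8)
    rgb[:, :, 1] = (v[:, :, 1] * 255).astype(np.uint8)
    return rgb
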