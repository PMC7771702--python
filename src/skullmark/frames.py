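"""Coordinate frames and the geometry linking them.

Four frames are used throughout the pipeline, all 0-based ``(row, col)``
with the origin at the top-left pixel centre:

``full``
    the raw photograph (default 2448 x 3264),
``lowres``
    the stage-one detection image, ``full`` downsampled by an integer
    factor (default 4, giving 612 x 816),
``crop``
    a fixed-size square window cut from ``full`` around the detected
    skull (default 640 x 640),
``net``
    the crop downsampled to the stage-two network input size (default
    256 x 256; crop/net scale 2.5).

:class:`CropWindow` records the geometry of one crop so that network
predictions can be mapped back to full-resolution coordinates exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .errors import FrameError, InvalidInputError

Coord = Tuple[float, float]

#: canonical frame identifiers
FRAMES = ("full", "lowres", "crop", "net")


@dataclass(frozen=True)
class LandmarkSet:
    """Bregma and lambda coordinates in a named frame.

    Bregma is the anterior landmark (sagittal x coronal suture
    intersection); lambda is the posterior one (sagittal x lambdoid).
    """

    bregma: Coord
    lambda_: Coord
    frame: str = "full"

    def __post_init__(self):
        for name, c in (("bregma", self.bregma), ("lambda", self.lambda_)):
            arr = np.asarray(c, dtype=float)
            if arr.shape != (2,) or not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"{name} must be a finite (row, col) pair, got {c!r}")
            if np.any(arr < 0):
                raise InvalidInputError(f"{name} must be non-negative, got {c!r}")
        if tuple(self.bregma) == tuple(self.lambda_):
            raise InvalidInputError("bregma and lambda must be distinct points")
        if self.frame not in FRAMES:
            raise FrameError(f"unknown frame {self.frame!r}; expected one of {FRAMES}")

    @classmethod
    def unchecked(cls, bregma: Coord, lambda_: Coord, frame: str) -> "LandmarkSet":
        """Bypass validation; for degenerate decoder output (e.g. a constant
        heatmap argmaxes both channels to the same tie-break pixel)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "bregma", bregma)
        object.__setattr__(obj, "lambda_", lambda_)
        object.__setattr__(obj, "frame", frame)
        return obj

    def as_array(self) -> np.ndarray:
        """Return a (2, 2) array, row 0 = bregma, row 1 = lambda."""
        return np.array([self.bregma, self.lambda_], dtype=float)

    def with_frame(self, frame: str) -> "LandmarkSet":
        return replace(self, frame=frame)


@dataclass(frozen=True)
class CropWindow:
    """Geometry of one fixed-size crop taken from the full-resolution image.

    Parameters
    ----------
    origin : (row, col)
        Top-left corner of the crop in the full-resolution frame.
    crop_size : int
        Side length of the (square) crop in full-resolution pixels.
    net_size : int
        Side length after downsampling to the network input.
    """

    origin: Coord
    crop_size: int = 640
    net_size: int = 256

    def __post_init__(self):
        if self.crop_size <= 0 or self.net_size <= 0:
            raise InvalidInputError("crop_size and net_size must be positive")

    @property
    def scale(self) -> float:
        """Full-resolution pixels per net pixel (default 640/256 = 2.5)."""
        return self.crop_size / self.net_size

    # ---- point maps ----------------------------------------------------
    def net_to_full(self, coord: Coord) -> Coord:
        """Map a net-frame point to the full-resolution frame."""
        r, c = coord
        return (self.origin[0] + r * self.scale, self.origin[1] + c * self.scale)

    def full_to_net(self, coord: Coord) -> Coord:
        """Exact inverse of :meth:`net_to_full`."""
        r, c = coord
        return ((r - self.origin[0]) / self.scale, (c - self.origin[1]) / self.scale)

    def net_to_crop(self, coord: Coord) -> Coord:
        return (coord[0] * self.scale, coord[1] * self.scale)

    def crop_to_net(self, coord: Coord) -> Coord:
        return (coord[0] / self.scale, coord[1] / self.scale)

    def full_to_crop(self, coord: Coord) -> Coord:
        return (coord[0] - self.origin[0], coord[1] - self.origin[1])

    def crop_to_full(self, coord: Coord) -> Coord:
        return (coord[0] + self.origin[0], coord[1] + self.origin[1])

    def landmarks_to_crop(self, landmarks: LandmarkSet) -> LandmarkSet:
        if landmarks.frame != "full":
            raise FrameError(f"expected full-frame landmarks, got {landmarks.frame!r}")
        return LandmarkSet(
            bregma=self.full_to_crop(landmarks.bregma),
            lambda_=self.full_to_crop(landmarks.lambda_),
            frame="crop",
        )


def to_full(coord: Coord, window: CropWindow) -> Coord:
    """Map a net-frame coordinate to the full-resolution frame.

    ``full = origin + coord * (crop_size / net_size)``; extrapolation
    outside ``[0, net_size)`` is allowed (the caller may be mapping a
    point that strayed off the crop).
    """
    return window.net_to_full(coord)


def to_net(coord: Coord, window: CropWindow) -> Coord:
    """Inverse of :func:`to_full`."""
    return window.full_to_net(coord)


def lowres_bbox_to_full(bbox, factor: int = 4):
    """Scale a ``(row0, col0, row1, col1)`` box from the lowres to the full frame.

    The stage-one detector works on the 4x-downsampled image; its box is
    mapped back by multiplying every coordinate by the factor.
    """
    if factor < 1:
        raise InvalidInputError(f"factor must be >= 1, got {factor}")
    return tuple(v * factor for v in bbox)


def compute_crop_window(
    bbox_full,
    image_shape: Tuple[int, int],
    crop_size: int = 640,
    net_size: int = 256,
) -> CropWindow:
    """Fixed-size crop window centred on a detected skull box.

    The window is centred on the bbox centre and then translated the
    minimum distance needed to lie fully inside the image.  If the image
    is smaller than ``crop_size`` along an axis the window starts at a
    (possibly negative) origin and the extractor edge-pads; the origin is
    chosen to centre the image in the crop.

    Parameters
    ----------
    bbox_full : (row0, col0, row1, col1)
        Skull bounding box in the full-resolution frame.
    image_shape : (H, W)
        Full-resolution image size.
    """
    r0, c0, r1, c1 = map(float, bbox_full)
    if r1 <= r0 or c1 <= c0:
        raise InvalidInputError(f"degenerate bbox {bbox_full!r}")
    H, W = int(image_shape[0]), int(image_shape[1])
    if r1 < 0 or c1 < 0 or r0 > H or c0 > W:
        raise InvalidInputError("bbox does not intersect the image")

    origin = []
    for centre, size in (((r0 + r1) / 2.0, H), ((c0 + c1) / 2.0, W)):
        o = centre - crop_size / 2.0
        if size >= crop_size:
            o = min(max(o, 0.0), size - crop_size)  # translate inside
        else:
            o = (size - crop_size) / 2.0  # centre the short axis; pad later
        origin.append(float(np.floor(o + 0.5)) if size >= crop_size else o)
    return CropWindow(origin=(origin[0], origin[1]), crop_size=crop_size, net_size=net_size)
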