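"""Image loading, scale calibration, region extraction and point angles.

Coordinates follow the raster convention used throughout the package:
``(x, y)`` with ``x`` = column and ``y`` = row, 0-based, ``y`` increasing
downward.  Annotation files are one JSON per image; their polygons and
points replace the interactive clicks of a GUI workflow.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from skimage import draw as skdraw

from ._errors import ImageIOError, ValidationError

# Rec. 601 luma weights: the standard luminance combination for RGB -> gray.
_LUMA = np.array([0.2989, 0.5870, 0.1140])


@dataclass
class Annotation:
    """Per-image annotation: scale bar, leaf polygons, optional landmarks.

    Parameters
    ----------
    scale_points
        Two distinct ``(x, y)`` pixel coordinates on the ruler.
    scale_length
        Physical length in cm between the two scale points (> 0).
    leaf_polygons
        One closed pixel-coordinate polygon (>= 3 vertices) per leaf.
    landmark_sets
        Optional: per polygon, an ordered list of ``(x, y)`` landmarks.
        The order defines homology and must be planned consistently.
    tip_angle_points
        Optional: per polygon, exactly three points ``(a, vertex, b)``
        defining the leaf-tip angle.
    orientation_flag
        ``"length_major"`` (default, long axis vertical) or
        ``"width_major"`` (leaves wider than tall; long axis horizontal).
    """

    scale_points: Sequence[Sequence[float]]
    scale_length: float
    leaf_polygons: Sequence[Sequence[Sequence[float]]]
    landmark_sets: Sequence[Sequence[Sequence[float]]] | None = None
    tip_angle_points: Sequence[Sequence[Sequence[float]]] | None = None
    orientation_flag: str = "length_major"
    leaf_ids: Sequence[str] | None = field(default=None)

    def __post_init__(self) -> None:
        p1, p2 = self.scale_points
        if tuple(p1) == tuple(p2):
            raise ValidationError("scale_points must be distinct")
        if self.scale_length <= 0:
            raise ValidationError("scale_length must be positive")
        if self.orientation_flag not in ("length_major", "width_major"):
            raise ValidationError(
                f"orientation_flag must be 'length_major' or 'width_major', "
                f"got {self.orientation_flag!r}"
            )
        for i, poly in enumerate(self.leaf_polygons):
            if len(poly) < 3:
                raise ValidationError(f"polygon {i} has fewer than 3 vertices")
        if self.landmark_sets is not None:
            counts = {len(s) for s in self.landmark_sets if len(s) > 0}
            if len(counts) > 1:
                raise ValidationError(
                    "landmark count must be constant across leaves within a study"
                )
        if self.tip_angle_points is not None:
            for i, pts in enumerate(self.tip_angle_points):
                if pts is not None and len(pts) != 3:
                    raise ValidationError(
                        f"tip_angle_points for leaf {i} must have exactly 3 points"
                    )

    @classmethod
    def from_json(cls, path: str | Path) -> "Annotation":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            scale_points=payload["scale_points"],
            scale_length=payload["scale_length"],
            leaf_polygons=payload["leaf_polygons"],
            landmark_sets=payload.get("landmark_sets"),
            tip_angle_points=payload.get("tip_angle_points"),
            orientation_flag=payload.get("orientation_flag", "length_major"),
            leaf_ids=payload.get("leaf_ids"),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scale_points": [list(map(float, p)) for p in self.scale_points],
            "scale_length": float(self.scale_length),
            "leaf_polygons": [
                [list(map(float, v)) for v in poly] for poly in self.leaf_polygons
            ],
            "orientation_flag": self.orientation_flag,
        }
        if self.landmark_sets is not None:
            payload["landmark_sets"] = [
                [list(map(float, p)) for p in s] for s in self.landmark_sets
            ]
        if self.tip_angle_points is not None:
            payload["tip_angle_points"] = [
                None if pts is None else [list(map(float, p)) for p in pts]
                for pts in self.tip_angle_points
            ]
        if self.leaf_ids is not None:
            payload["leaf_ids"] = list(self.leaf_ids)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class CalibratedImage:
    """A grayscale raster plus its physical scale in cm per pixel."""

    pixels: np.ndarray
    scale: float
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError("scale must be positive")
        if self.pixels.size == 0:
            raise ValidationError("pixels must be non-empty")


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster; color channels are preserved."""
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"image file not found: {path}")
    try:
        return np.asarray(iio.imread(path))
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise ImageIOError(f"could not read image {path}: {exc}") from exc


def calibrate_scale(
    p1: Sequence[float], p2: Sequence[float], known_length: float
) -> float:
    """cm-per-pixel scale from two ruler points a known length apart.

    One calibration is reused for every leaf in the image.
    """
    if known_length <= 0:
        raise ValidationError("known_length must be positive")
    dist = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
    if dist == 0:
        raise ValidationError("calibration points must be distinct")
    return known_length / dist


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) raster to one luminance channel.

    Already-gray input is returned unchanged.  Color input uses the
    Rec. 601 weights (0.299 R + 0.587 G + 0.114 B); an alpha channel,
    if present, is dropped.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        rgb = image[..., :3].astype(float)
        gray = rgb @ _LUMA
        if np.issubdtype(image.dtype, np.integer):
            info = np.iinfo(image.dtype)
            gray = np.clip(np.rint(gray), info.min, info.max).astype(image.dtype)
        return gray
    if image.ndim == 3 and image.shape[2] == 1:
        return image[..., 0]
    raise ValidationError(
        f"unsupported channel count for grayscale conversion: shape {image.shape}"
    )


def _polygon_mask(shape: tuple[int, int], polygon: np.ndarray) -> np.ndarray:
    """Boolean inside-polygon raster; boundary pixels count as inside."""
    rows = polygon[:, 1]
    cols = polygon[:, 0]
    mask = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.polygon(rows, cols, shape=shape)
    mask[rr, cc] = True
    # polygon() can exclude pixels exactly on the boundary; add them.
    rr, cc = skdraw.polygon_perimeter(rows, cols, shape=shape, clip=True)
    mask[rr, cc] = True
    return mask


def extract_region(
    image: np.ndarray, polygon: Sequence[Sequence[float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Crop to the polygon's bounding box, whitening out-of-polygon pixels.

    Returns ``(region, region_mask)`` where ``region_mask`` marks
    inside-polygon pixels of the crop.  Background fill is the maximum
    intensity (white), matching a light scanner background so that
    thresholding treats it as exterior.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError("extract_region expects a 2-D grayscale image")
    poly = np.asarray(polygon, dtype=float)
    if poly.shape[0] < 3:
        raise ValidationError("polygon needs at least 3 vertices")
    h, w = image.shape
    if (
        poly[:, 0].max() < 0
        or poly[:, 0].min() > w - 1
        or poly[:, 1].max() < 0
        or poly[:, 1].min() > h - 1
    ):
        raise ValidationError("polygon lies fully outside the image")
    mask = _polygon_mask(image.shape, poly)
    if not mask.any():
        raise ValidationError("polygon lies fully outside the image")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    sub_mask = mask[r0:r1, c0:c1]
    region = image[r0:r1, c0:c1].copy()
    if np.issubdtype(image.dtype, np.integer):
        white = np.iinfo(image.dtype).max
    else:
        white = float(image.max()) if image.size else 1.0
    region[~sub_mask] = white
    return region, sub_mask


def measure_angle(
    a: Sequence[float], vertex: Sequence[float], b: Sequence[float]
) -> float:
    """Interior angle (degrees, [0, 180]) at *vertex* between rays to a and b."""
    va = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    vb = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    if not va.any() or not vb.any():
        raise ValidationError("angle points must not coincide with the vertex")
    # atan2 of (|cross|, dot) is stable near 0 and 180 degrees, unlike arccos
    cross = va[0] * vb[1] - va[1] * vb[0]
    dot = float(np.dot(va, vb))
    return float(np.degrees(np.arctan2(abs(cross), dot)))
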