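"""Binarization, mask cleanup, principal axes and standard orientation.

The leaf is segmented from the selected region by a global automatic
threshold (Otsu on in-region pixels), holes are filled and only the
largest connected component kept.  The second-central-moment tensor of
the foreground gives the centroid and principal axes; the mask is then
rotated about its centroid so the major axis is vertical (or horizontal
for leaves annotated as wider than long).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage import transform as sktransform
from skimage.filters import threshold_otsu

from ._errors import SegmentationError, ValidationError

# Elongation (major/minor eigenvalue ratio) below which the shape is
# treated as isotropic and no rotation is attempted.
ISOTROPY_RATIO = 1.02

#: Alignment is accepted when the remeasured major axis is within this
#: many degrees of the target direction.
ALIGN_TOL_DEG = 0.5


@dataclass
class LeafMask:
    """Binary leaf raster (True = interior) with scale and axis metadata."""

    mask: np.ndarray
    scale: float
    centroid: tuple[float, float]
    axis_angle: float
    aligned: bool = False
    leaf_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValidationError("LeafMask must contain at least one foreground pixel")
        if self.scale <= 0:
            raise ValidationError("scale must be positive")


class AxisInfo(NamedTuple):
    centroid: tuple[float, float]  # (x, y) pixel coordinates
    angle_deg: float  # major axis vs. vertical, in (-90, 90]; nan if isotropic
    elongation: float  # major/minor eigenvalue ratio (>= 1)

    @property
    def isotropic(self) -> bool:
        return self.elongation < ISOTROPY_RATIO


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = skmeasure.label(mask, connectivity=2, return_num=True)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def binarize(
    gray: np.ndarray,
    region_mask: np.ndarray | None = None,
    polarity: str = "dark_leaf",
    scale: float = 1.0,
    threshold: float | None = None,
    leaf_id: str = "",
) -> LeafMask:
    """Threshold the selected region into a clean single-component mask.

    The global threshold is computed by Otsu's method on in-region
    pixels unless an explicit ``threshold`` override is given.  The
    leaf-side class is chosen by ``polarity`` (``dark_leaf``: leaf darker
    than background, the common case for pressed leaves on a light
    scanner bed).  Holes are filled and only the largest connected
    component survives; fragmentation is resolved in the leaf's favor
    and reported via a warning.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValidationError("binarize expects a 2-D grayscale image")
    if polarity not in ("dark_leaf", "light_leaf"):
        raise ValidationError(f"unknown polarity {polarity!r}")
    if region_mask is None:
        region_mask = np.ones(gray.shape, dtype=bool)
    sample = gray[region_mask]
    if sample.size == 0:
        raise ValidationError("region mask selects no pixels")
    if threshold is None:
        if np.ptp(sample) == 0:
            raise SegmentationError(
                "region has uniform intensity; no threshold separates leaf from "
                "background — override with an explicit threshold or fix polarity"
            )
        threshold = float(threshold_otsu(sample))
    # Otsu's value is the top of the lower class: dark pixels are <= t
    if polarity == "dark_leaf":
        fg = gray <= threshold
    else:
        fg = gray > threshold
    fg &= region_mask
    if not fg.any():
        raise SegmentationError(
            "thresholding produced an empty foreground — try the opposite "
            "polarity or an explicit threshold override"
        )
    fg = ndi.binary_fill_holes(fg)
    labels, n = skmeasure.label(fg, connectivity=2, return_num=True)
    if n > 1:
        warnings.warn(
            f"threshold split the leaf into {n} fragments; "
            "keeping only the largest component",
            stacklevel=2,
        )
        fg = _largest_component(fg)
    info = centroid_and_axes(fg)
    return LeafMask(
        mask=fg,
        scale=scale,
        centroid=info.centroid,
        axis_angle=info.angle_deg,
        aligned=False,
        leaf_id=leaf_id,
    )


def centroid_and_axes(mask: np.ndarray) -> AxisInfo:
    """Centroid and principal-axis orientation of a boolean mask.

    The angle is that of the major eigenvector of the 2x2
    second-central-moment matrix of foreground pixel coordinates,
    reported in degrees relative to vertical (the image row axis),
    in (-90, 90].  Positive angles tilt the downward axis direction
    toward +x.  Isotropic shapes (eigenvalue ratio < 1.02) get
    ``angle_deg = nan``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    rows, cols = np.nonzero(mask)
    cr, cc = rows.mean(), cols.mean()
    dr, dc = rows - cr, cols - cc
    cov = np.array(
        [[np.mean(dr * dr), np.mean(dr * dc)], [np.mean(dr * dc), np.mean(dc * dc)]]
    )
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = evals
    v = evecs[:, 1]  # (vr, vc) of the major axis
    elongation = float(lam_major / lam_minor) if lam_minor > 0 else np.inf
    if elongation < ISOTROPY_RATIO:
        return AxisInfo((float(cc), float(cr)), float("nan"), elongation)
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    angle = float(np.degrees(np.arctan2(v[1], v[0])))
    if angle <= -90.0:
        angle += 180.0
    return AxisInfo((float(cc), float(cr)), angle, elongation)


def _pad_for_rotation(mask: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    diag = int(np.ceil(np.hypot(h, w)))
    pr = (diag - h) // 2 + 2
    pc = (diag - w) // 2 + 2
    return np.pad(mask, ((pr, pr), (pc, pc)))


def align(leaf: LeafMask, orientation_flag: str = "length_major") -> LeafMask:
    """Rotate the leaf about its centroid into standard orientation.

    ``length_major`` puts the major principal axis vertical;
    ``width_major`` puts it horizontal.  Rotation uses nearest-neighbor
    interpolation so the mask stays binary.  The measurement and
    rotation are iterated (raster rotation is not exact) until the
    remeasured axis is within 0.5 degrees of the target.  The 180-degree
    principal-axis ambiguity is deliberately left unresolved; downstream
    EFD normalization and Procrustes handle rotation-invariant
    comparison.
    """
    if orientation_flag not in ("length_major", "width_major"):
        raise ValidationError(f"unknown orientation_flag {orientation_flag!r}")
    target = 0.0 if orientation_flag == "length_major" else 90.0
    mask = _pad_for_rotation(leaf.mask)
    info = centroid_and_axes(mask)
    if info.isotropic:
        warnings.warn(
            "shape is isotropic (eigenvalue ratio < 1.02); no rotation applied",
            stacklevel=2,
        )
        return LeafMask(
            mask=mask,
            scale=leaf.scale,
            centroid=info.centroid,
            axis_angle=info.angle_deg,
            aligned=True,
            leaf_id=leaf.leaf_id,
        )
    for _ in range(5):
        delta = info.angle_deg - target
        # map the residual into (-90, 90]: axes are undirected
        if delta > 90.0:
            delta -= 180.0
        elif delta <= -90.0:
            delta += 180.0
        if abs(delta) < 0.1:
            break
        # skimage rotates CCW in display coords; content rotation by
        # -delta about the centroid brings the major axis onto target.
        mask = (
            sktransform.rotate(
                mask.astype(float),
                angle=-delta,
                center=info.centroid,
                order=0,
                preserve_range=True,
            )
            > 0.5
        )
        mask = ndi.binary_fill_holes(mask)
        mask = _largest_component(mask)
        info = centroid_and_axes(mask)
        if info.isotropic:
            break
    residual = info.angle_deg - target
    if not info.isotropic:
        if residual > 90.0:
            residual -= 180.0
        elif residual <= -90.0:
            residual += 180.0
        if abs(residual) > ALIGN_TOL_DEG:
            warnings.warn(
                f"alignment residual {residual:.2f} deg exceeds "
                f"{ALIGN_TOL_DEG} deg",
                stacklevel=2,
            )
    return LeafMask(
        mask=mask,
        scale=leaf.scale,
        centroid=info.centroid,
        axis_angle=info.angle_deg,
        aligned=True,
        leaf_id=leaf.leaf_id,
    )
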