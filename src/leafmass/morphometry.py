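"""Simple measurements on an aligned leaf mask.

Length and width come from the bounding box of the upright leaf, area
from the foreground pixel count, and fluctuating asymmetry (FA) from
the per-row left/right widths about the central vertical axis:

    FA = 2 (WL - WR) / (WL + WR)

where WL and WR are the distances from the vertical line through the
centroid to the leaf's left and right margins on that row.  FA = 0 is
perfect bilateral symmetry; positive values skew left of center,
negative values right.  The summary statistic is the mean of |FA| over
rows, one value per leaf, in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .segmentation import LeafMask, centroid_and_axes


@dataclass
class LeafMeasurements:
    leaf_id: str
    length: float  # cm
    width: float  # cm
    area: float  # cm^2
    mean_abs_FA: float  # dimensionless, [0, 2]
    tip_angle: float | None = None  # degrees

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0 or self.area <= 0:
            raise ValidationError("length, width and area must be positive")
        if not (0.0 <= self.mean_abs_FA <= 2.0):
            raise ValidationError("mean_abs_FA must lie in [0, 2]")


@dataclass
class AsymmetryProfile:
    """Per-row widths and FA values; rows with zero total width excluded."""

    rows: np.ndarray  # row indices
    WL: np.ndarray  # px, distance centroid-axis -> left margin (>= 0)
    WR: np.ndarray  # px, distance centroid-axis -> right margin (>= 0)
    FA: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = self.WL + self.WR
        if np.any(total <= 0):
            raise ValidationError("rows with WL + WR <= 0 must be excluded")
        self.FA = 2.0 * (self.WL - self.WR) / total

    @property
    def mean_abs_FA(self) -> float:
        return float(np.mean(np.abs(self.FA)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"row": self.rows, "WL_px": self.WL, "WR_px": self.WR, "FA": self.FA}
        )


def _require_aligned(leaf: LeafMask) -> None:
    if not leaf.aligned:
        raise ValidationError("measurement requires an aligned LeafMask")


def bounding_box_measures(
    leaf: LeafMask, orientation_flag: str = "length_major"
) -> tuple[float, float]:
    """(length_cm, width_cm) of the upright leaf's bounding box.

    Extents are inclusive pixel counts times the scale.  Under
    ``width_major`` the leaf was aligned with its long axis horizontal,
    so the column extent is reported as the length.
    """
    _require_aligned(leaf)
    rows, cols = np.nonzero(leaf.mask)
    v_extent = (rows.max() - rows.min() + 1) * leaf.scale
    h_extent = (cols.max() - cols.min() + 1) * leaf.scale
    if orientation_flag == "width_major":
        return float(h_extent), float(v_extent)
    return float(v_extent), float(h_extent)


def area(leaf: LeafMask) -> float:
    """Leaf area in cm^2: foreground pixel count times scale squared."""
    if not leaf.mask.any():
        raise ValidationError("mask is empty")
    return float(leaf.mask.sum()) * leaf.scale**2


def fluctuating_asymmetry(
    leaf: LeafMask, orientation_flag: str = "length_major"
) -> tuple[AsymmetryProfile, float]:
    """Per-row FA profile and the mean absolute FA of the leaf.

    The central vertical axis is the vertical line through the
    foreground centroid.  WL/WR are measured to the outermost margin
    pixel of each row (interior holes are filled upstream).  Rows lying
    entirely on one side of the axis have the off-side distance clamped
    to zero, giving FA = +/-2, and are included in the mean; single-pixel
    rows (zero total width) are excluded.  With ``width_major`` the leaf
    lies horizontally and the roles of rows and columns transpose.
    """
    _require_aligned(leaf)
    mask = leaf.mask
    if orientation_flag == "width_major":
        mask = mask.T  # axis roles transpose; "rows" are image columns
    info = centroid_and_axes(mask)
    axis_x = info.centroid[0]
    ny = mask.shape[0]
    rows_idx, WL, WR = [], [], []
    for r in range(ny):
        cols = np.flatnonzero(mask[r])
        if cols.size == 0:
            continue
        wl = axis_x - cols[0]
        wr = cols[-1] - axis_x
        # row entirely on one side: clamp the off-side distance so FA = +/-2
        wl, wr = max(wl, 0.0), max(wr, 0.0)
        if wl + wr <= 0:
            continue
        rows_idx.append(r)
        WL.append(wl)
        WR.append(wr)
    if not rows_idx:
        raise ValidationError("no rows with positive width; cannot compute FA")
    profile = AsymmetryProfile(
        rows=np.asarray(rows_idx), WL=np.asarray(WL), WR=np.asarray(WR)
    )
    return profile, profile.mean_abs_FA


def measure_leaf(
    leaf: LeafMask,
    orientation_flag: str = "length_major",
    tip_angle: float | None = None,
) -> LeafMeasurements:
    """Bundle bounding-box, area and FA measurements for one leaf."""
    length, width = bounding_box_measures(leaf, orientation_flag)
    _, fa = fluctuating_asymmetry(leaf, orientation_flag)
    return LeafMeasurements(
        leaf_id=leaf.leaf_id,
        length=length,
        width=width,
        area=area(leaf),
        mean_abs_FA=fa,
        tip_angle=tip_angle,
    )
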