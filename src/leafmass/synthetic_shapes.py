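"""Parametric leaf-like fixtures with analytic ground truth.

Leaves are generated from a polar outline about the origin,

    r(phi) = r_ellipse(phi) * (1 + lobe_depth cos(n_lobes phi))
                            * (1 - skew sin(phi)) * (1 + noise(phi)),

with phi the angle from the apex (+y) direction.  The ellipse base sets
length and width; the cosine term adds palmate-style lobes; the odd skew
term widens the left side for positive skew (so measured FA is
positive); noise is a low-order random Fourier perturbation behind one
explicit seed.  Because the outline is star-shaped it never
self-intersects while r > 0.

The analytic outline provides ground-truth length, width, area,
fluctuating asymmetry (via exact scanline intersections of the polygon)
and landmark positions (the lobe-modulation extrema), so every pipeline
stage can be tested without real leaf images.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Polygon

from ._errors import ValidationError
from .landmarks import LandmarkSet
from .morphometry import LeafMeasurements
from .outline_efd import Contour
from .segmentation import LeafMask

_DENSE = 2048  # outline samples used for rasterization and ground truth


@dataclass
class LeafSpec:
    """Parameters of one synthetic leaf.

    length_px / width_px are the axes of the base ellipse in pixels;
    lobe_depth is the fractional lobe amplitude in [0, 1); skew in
    (-1, 1) controls left-right asymmetry (positive = left side wider);
    noise_amp is the fractional boundary perturbation; rotation_deg
    rotates the rasterized leaf counter-clockwise; scale converts
    pixels to cm for exported measurements.
    """

    length_px: int = 200
    width_px: int = 100
    n_lobes: int = 0
    lobe_depth: float = 0.0
    skew: float = 0.0
    rotation_deg: float = 0.0
    noise_amp: float = 0.0
    seed: int = 0
    scale: float = 1.0
    leaf_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.length_px <= 2 or self.width_px <= 2:
            raise ValidationError("length_px and width_px must exceed 2 pixels")
        if not (0.0 <= self.lobe_depth < 1.0):
            raise ValidationError("lobe_depth must lie in [0, 1)")
        if not (-1.0 < self.skew < 1.0):
            raise ValidationError("skew must lie in (-1, 1)")
        if self.n_lobes < 0:
            raise ValidationError("n_lobes must be >= 0")
        if self.noise_amp < 0:
            raise ValidationError("noise_amp must be >= 0")


def _radius(spec: LeafSpec, phi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    a = spec.length_px / 2.0  # semi-axis along y (apex direction)
    b = spec.width_px / 2.0
    r = a * b / np.sqrt((a * np.sin(phi)) ** 2 + (b * np.cos(phi)) ** 2)
    mod = np.ones_like(phi)
    if spec.n_lobes > 0 and spec.lobe_depth > 0:
        mod *= 1.0 + spec.lobe_depth * np.cos(spec.n_lobes * phi)
    mod *= 1.0 - spec.skew * np.sin(phi)
    if spec.noise_amp > 0:
        # smooth seeded perturbation: random low-order harmonics
        for k in range(2, 7):
            amp = rng.normal(0.0, spec.noise_amp / np.sqrt(5))
            psi = rng.uniform(0.0, 2.0 * np.pi)
            mod *= 1.0 + amp * np.cos(k * phi + psi)
    r = r * mod
    if np.any(r <= 1.0):
        raise ValidationError(
            "outline parameters drive the radius to zero (self-intersecting "
            "outline); reduce lobe_depth, |skew| or noise_amp"
        )
    return r


def _analytic_outline(spec: LeafSpec, rng: np.random.Generator) -> np.ndarray:
    """Dense (x, y) outline in math convention, unrotated, origin-centered."""
    phi = np.linspace(0.0, 2.0 * np.pi, _DENSE, endpoint=False)
    r = _radius(spec, phi, rng)
    return np.column_stack([r * np.sin(phi), r * np.cos(phi)])


def _rotate(points: np.ndarray, deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return points @ R.T


def _analytic_fa(outline: np.ndarray, n_rows: int = 201) -> float:
    """Ground-truth mean |FA| by exact scanline intersection of the polygon."""
    poly = Polygon(outline)
    cx = poly.centroid.x
    ymin, ymax = outline[:, 1].min(), outline[:, 1].max()
    xmin, xmax = outline[:, 0].min() - 1, outline[:, 0].max() + 1
    fas = []
    for y in np.linspace(ymin, ymax, n_rows + 2)[1:-1]:
        seg = poly.intersection(LineString([(xmin, y), (xmax, y)]))
        if seg.is_empty:
            continue
        x0, _, x1, _ = seg.bounds
        wl, wr = max(cx - x0, 0.0), max(x1 - cx, 0.0)
        if wl + wr > 0:
            fas.append(2.0 * (wl - wr) / (wl + wr))
    return float(np.mean(np.abs(fas))) if fas else 0.0


def _landmark_angles(spec: LeafSpec) -> np.ndarray:
    if spec.n_lobes >= 1:
        # extrema of the cosine lobe modulation: n tips (apex included)
        # alternating with n sinuses (base included), clockwise from apex
        return np.arange(2 * spec.n_lobes) * np.pi / spec.n_lobes
    # entire leaf: apex, right, base, left extrema of the ellipse
    return np.array([0.0, 0.5, 1.0, 1.5]) * np.pi


def generate_leaf(
    spec: LeafSpec,
) -> tuple[LeafMask, Contour, LandmarkSet, LeafMeasurements]:
    """Rasterize one synthetic leaf and return it with its ground truth.

    Returns ``(mask, analytic_outline, landmarks, truth)`` where the
    outline is the dense analytic polygon (as a float coordinate
    sequence in raster (x, y) pixel coordinates), landmarks sit at the
    analytic lobe extrema, and ``truth`` holds length/width/area/FA
    computed from the analytic outline (not from the raster).
    """
    rng = np.random.default_rng(spec.seed)
    outline = _analytic_outline(spec, rng)

    # ground truth from the unrotated analytic polygon
    length_px = float(np.ptp(outline[:, 1]))
    width_px = float(np.ptp(outline[:, 0]))
    area_px = float(Polygon(outline).area)
    fa_truth = _analytic_fa(outline)
    truth = LeafMeasurements(
        leaf_id=spec.leaf_id,
        length=length_px * spec.scale,
        width=width_px * spec.scale,
        area=area_px * spec.scale**2,
        mean_abs_FA=min(fa_truth, 2.0),
    )

    rotated = _rotate(outline, spec.rotation_deg)
    margin = 6
    # integer center column/row: keeps the raster exactly mirror-symmetric
    # about a pixel column when the outline is symmetric (skew = 0, rot 0)
    cx = float(np.ceil(-rotated[:, 0].min()) + margin)
    cy = float(np.ceil(rotated[:, 1].max()) + margin)
    cols = rotated[:, 0] + cx
    rows = cy - rotated[:, 1]  # math y-up -> raster row
    h = int(np.ceil(rows.max())) + margin + 1
    w = int(np.ceil(cols.max())) + margin + 1
    # analytic star-shaped rasterization: a pixel is leaf iff its radius
    # (in the unrotated frame) is within the outline radius at its angle.
    # This is deterministic and preserves mirror symmetry exactly.
    yy, xx = np.mgrid[0:h, 0:w]
    px = xx - cx
    py = cy - yy
    th = np.deg2rad(spec.rotation_deg)
    x0 = np.cos(th) * px + np.sin(th) * py  # rotate back by -rotation_deg
    y0 = -np.sin(th) * px + np.cos(th) * py
    phi_grid = np.mod(np.arctan2(x0, y0), 2.0 * np.pi)
    phi_dense = np.linspace(0.0, 2.0 * np.pi, _DENSE, endpoint=False)
    r_dense = np.hypot(outline[:, 0], outline[:, 1])
    r_at = np.interp(
        phi_grid.ravel(),
        np.concatenate([phi_dense, [2.0 * np.pi]]),
        np.concatenate([r_dense, [r_dense[0]]]),
    ).reshape(phi_grid.shape)
    mask = np.hypot(x0, y0) <= r_at

    fg_rows, fg_cols = np.nonzero(mask)
    centroid = (float(fg_cols.mean()), float(fg_rows.mean()))
    leaf = LeafMask(
        mask=mask,
        scale=spec.scale,
        centroid=centroid,
        axis_angle=float(spec.rotation_deg),
        aligned=(spec.rotation_deg % 180.0 == 0.0),
        leaf_id=spec.leaf_id,
    )

    # landmarks at analytic lobe extrema, mapped into raster coordinates
    ang = _landmark_angles(spec)
    rng_lm = np.random.default_rng(spec.seed)  # same noise realization
    r_lm = _radius(spec, ang, rng_lm)
    lm_math = np.column_stack([r_lm * np.sin(ang), r_lm * np.cos(ang)])
    lm_rot = _rotate(lm_math, spec.rotation_deg)
    lm_px = np.column_stack([lm_rot[:, 0] + cx, cy - lm_rot[:, 1]])
    landmarks = LandmarkSet(leaf_id=spec.leaf_id, points=lm_px)

    outline_px = np.column_stack([cols, rows])
    contour = Contour.from_float_polygon(outline_px)
    return leaf, contour, landmarks, truth


def generate_population(
    base: LeafSpec,
    n: int,
    variation: dict[str, float] | None = None,
    seed: int = 0,
) -> list[tuple[LeafMask, Contour, LandmarkSet, LeafMeasurements]]:
    """Generate ``n`` leaves with parameters jittered around ``base``.

    ``variation`` maps LeafSpec field names to Gaussian standard
    deviations (absolute units).  Each leaf draws its own boundary-noise
    seed from the population seed, so the run is fully reproducible.
    """
    if n < 2:
        raise ValidationError("a population needs n >= 2 leaves")
    rng = np.random.default_rng(seed)
    variation = dict(variation or {})
    leaves = []
    for i in range(n):
        params: dict[str, float] = {}
        for name, sd in variation.items():
            if not hasattr(base, name):
                raise ValidationError(f"unknown LeafSpec field {name!r}")
            val = getattr(base, name) + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            if name in ("length_px", "width_px"):
                val = max(int(round(val)), 3)
            elif name == "lobe_depth":
                val = float(np.clip(val, 0.0, 0.95))
            elif name == "skew":
                val = float(np.clip(val, -0.9, 0.9))
            elif name == "noise_amp":
                val = max(float(val), 0.0)
            params[name] = val
        spec = replace(
            base,
            **params,
            seed=int(rng.integers(0, 2**31 - 1)),
            leaf_id=f"{base.leaf_id}_{i:03d}",
        )
        leaves.append(generate_leaf(spec))
    return leaves
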