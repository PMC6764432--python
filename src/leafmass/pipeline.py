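"""Per-leaf processing shared by the CLI and scripted analyses.

One call takes a calibrated grayscale image plus one annotation polygon
through segmentation, alignment, measurement, and elliptical Fourier
description; batch helpers assemble the standard CSV tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import Annotation, extract_region, measure_angle
from .morphometry import AsymmetryProfile, LeafMeasurements, measure_leaf
from .outline_efd import (
    ChainCode,
    Contour,
    EFDSet,
    contour_to_chain_code,
    efd_fit,
    normalize_efd,
    reconstruct_outline,
    trace_boundary,
)
from .segmentation import LeafMask, align, binarize
from . import morphometry

DEFAULT_HARMONICS = 15  # 15-20 harmonics typically suffice for leaf outlines


@dataclass
class LeafResult:
    leaf_id: str
    mask: LeafMask
    measurements: LeafMeasurements
    asymmetry: AsymmetryProfile
    contour: Contour
    chain: ChainCode
    efd: EFDSet  # normalized
    efd_raw: EFDSet  # unnormalized


def mask_to_efd(
    leaf: LeafMask, n_harmonics: int = DEFAULT_HARMONICS
) -> tuple[Contour, ChainCode, EFDSet, EFDSet]:
    """Trace an aligned mask and fit normalized EFDs.

    Returns ``(contour, chain, efd_raw, efd_normalized)``.  The mask is
    padded so the foreground never touches the border during tracing.
    """
    padded = LeafMask(
        mask=np.pad(leaf.mask, 2),
        scale=leaf.scale,
        centroid=(leaf.centroid[0] + 2, leaf.centroid[1] + 2),
        axis_angle=leaf.axis_angle,
        aligned=leaf.aligned,
        leaf_id=leaf.leaf_id,
    )
    contour = trace_boundary(padded)
    chain = contour_to_chain_code(contour)
    efd_raw = efd_fit(chain, n_harmonics, leaf_id=leaf.leaf_id)
    return contour, chain, efd_raw, normalize_efd(efd_raw)


def process_leaf(
    gray: np.ndarray,
    polygon,
    scale: float,
    leaf_id: str = "",
    orientation_flag: str = "length_major",
    polarity: str = "dark_leaf",
    threshold: float | None = None,
    n_harmonics: int = DEFAULT_HARMONICS,
    tip_points=None,
) -> LeafResult:
    """Full single-leaf pipeline: region -> mask -> measurements -> EFD."""
    region, region_mask = extract_region(gray, polygon)
    raw = binarize(
        region, region_mask, polarity=polarity, scale=scale,
        threshold=threshold, leaf_id=leaf_id,
    )
    aligned = align(raw, orientation_flag)
    tip_angle = None
    if tip_points is not None:
        a, v, b = tip_points
        tip_angle = measure_angle(a, v, b)
    meas = measure_leaf(aligned, orientation_flag, tip_angle=tip_angle)
    profile, _ = morphometry.fluctuating_asymmetry(aligned, orientation_flag)
    contour, chain, efd_raw, efd_norm = mask_to_efd(aligned, n_harmonics)
    return LeafResult(
        leaf_id=leaf_id,
        mask=aligned,
        measurements=meas,
        asymmetry=profile,
        contour=contour,
        chain=chain,
        efd=efd_norm,
        efd_raw=efd_raw,
    )


def process_annotation(
    gray: np.ndarray,
    annotation: Annotation,
    scale: float,
    n_harmonics: int = DEFAULT_HARMONICS,
    polarity: str = "dark_leaf",
    threshold: float | None = None,
) -> tuple[list[LeafResult], list[tuple[str, Exception]]]:
    """Process every polygon in an annotation; failures are collected."""
    results: list[LeafResult] = []
    failures: list[tuple[str, Exception]] = []
    ids = annotation.leaf_ids or [
        f"leaf_{i:03d}" for i in range(len(annotation.leaf_polygons))
    ]
    for i, polygon in enumerate(annotation.leaf_polygons):
        tip = None
        if annotation.tip_angle_points is not None:
            candidate = annotation.tip_angle_points[i]
            tip = candidate if candidate else None
        try:
            results.append(
                process_leaf(
                    gray,
                    polygon,
                    scale,
                    leaf_id=ids[i],
                    orientation_flag=annotation.orientation_flag,
                    polarity=polarity,
                    threshold=threshold,
                    n_harmonics=n_harmonics,
                    tip_points=tip,
                )
            )
        except Exception as exc:  # per-leaf failures must not kill the batch
            failures.append((ids[i], exc))
    return results, failures


def measurements_table(results: list[LeafResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        m = r.measurements
        rows.append(
            {
                "leaf_id": m.leaf_id,
                "length_cm": m.length,
                "width_cm": m.width,
                "area_cm2": m.area,
                "mean_abs_FA": m.mean_abs_FA,
                "tip_angle_deg": m.tip_angle if m.tip_angle is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def efd_table(results: list[LeafResult]) -> pd.DataFrame:
    """Long-format normalized coefficients: leaf_id, n, a, b, c, d."""
    return pd.concat([r.efd.to_frame() for r in results], ignore_index=True)


def outline_table(results: list[LeafResult], n_points: int = 256) -> pd.DataFrame:
    frames = []
    for r in results:
        pts = reconstruct_outline(r.efd, n_points)
        frames.append(
            pd.DataFrame(
                {
                    "leaf_id": r.leaf_id,
                    "t_index": np.arange(n_points),
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def efd_sets_from_table(df: pd.DataFrame, normalized: bool = True) -> list[EFDSet]:
    """Rebuild EFDSets from a long-format coefficient table."""
    for col in ("leaf_id", "n", "a", "b", "c", "d"):
        if col not in df.columns:
            raise KeyError(f"EFD table is missing column {col!r}")
    sets = []
    for leaf_id, grp in df.groupby("leaf_id", sort=False):
        grp = grp.sort_values("n")
        sets.append(
            EFDSet(
                n_harmonics=len(grp),
                coefficients=grp[["a", "b", "c", "d"]].to_numpy(),
                offset=(0.0, 0.0),
                normalized=normalized,
                leaf_id=str(leaf_id),
            )
        )
    return sets
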