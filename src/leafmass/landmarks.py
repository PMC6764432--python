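"""Landmark sets, connection-pair parsing and generalized Procrustes analysis.

Landmarks are ordered 2-D points whose order encodes homology across
specimens (e.g. the lobe tips of maple leaves, selected in a planned
sequence).  Generalized Procrustes analysis (GPA) superimposes the
configurations by removing translation (centroid to origin), size
(centroid size to 1) and rotation (least-squares, reflections
disallowed), then iterates mean-shape estimation to convergence.  The
per-landmark Euclidean distances from each aligned specimen to the mean
shape ("shift distances") are the default feature space for PCA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import ParseError, ValidationError


@dataclass
class LandmarkSet:
    """Ordered landmark coordinates for one leaf; order is homology."""

    leaf_id: str
    points: np.ndarray  # (K, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("landmark points must be an (K, 2) array")
        if len(self.points) < 3:
            raise ValidationError("need at least 3 landmarks")

    @property
    def k(self) -> int:
        return len(self.points)


@dataclass
class ConnectionSpec:
    """Landmark index pairs (1-based, as authored) to draw as segments."""

    pairs: list[tuple[int, int]]


@dataclass
class ProcrustesResult:
    aligned_sets: np.ndarray  # (n, K, 2)
    mean_shape: np.ndarray  # (K, 2), centroid at origin, centroid size 1
    shift_distances: np.ndarray  # (n, K)
    leaf_ids: list[str]
    n_iterations: int
    converged: bool


_PAIR_RE = re.compile(r"\[\s*(\d+)[\s,]+(\d+)\s*\]")


def parse_connections(text: str, n_landmarks: int | None = None) -> ConnectionSpec:
    """Parse a ``"[i j];[i j];..."`` connection string.

    Each connected pair is listed within square brackets, pairs
    separated by semicolons; whitespace is tolerated anywhere.
    Indices are 1-based.
    """
    stripped = text.strip()
    if not stripped:
        return ConnectionSpec(pairs=[])
    pairs: list[tuple[int, int]] = []
    pos = 0
    for chunk in stripped.split(";"):
        chunk_s = chunk.strip()
        if not chunk_s:
            pos += len(chunk) + 1
            continue
        m = _PAIR_RE.fullmatch(chunk_s)
        if not m:
            raise ParseError(
                f"malformed connection pair {chunk_s!r} near position {pos}"
            )
        i, j = int(m.group(1)), int(m.group(2))
        if i < 1 or j < 1:
            raise ParseError(f"landmark indices are 1-based; got ({i}, {j})")
        if i == j:
            raise ParseError(f"connection pair ({i}, {j}) links a landmark to itself")
        if n_landmarks is not None and (i > n_landmarks or j > n_landmarks):
            raise ParseError(
                f"connection pair ({i}, {j}) exceeds landmark count {n_landmarks}"
            )
        pairs.append((i, j))
        pos += len(chunk) + 1
    return ConnectionSpec(pairs=pairs)


def _center_and_size(points: np.ndarray) -> tuple[np.ndarray, float]:
    centered = points - points.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    return centered, size


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation (no reflection) mapping source onto target."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def generalized_procrustes(
    sets: Sequence[LandmarkSet],
    tol: float = 1e-10,
    max_iter: int = 100,
    remove_scale: bool = True,
) -> ProcrustesResult:
    """Superimpose landmark configurations and estimate the mean shape.

    Translation is removed by centering, size by centroid-size
    normalization (optional via ``remove_scale``), rotation by the
    least-squares orthogonal fit with reflections disallowed.  The mean
    shape is re-estimated until its RMS change falls below ``tol``.
    """
    if len(sets) < 2:
        raise ValidationError("GPA needs at least 2 landmark sets")
    k = sets[0].k
    if any(s.k != k for s in sets):
        raise ValidationError("all landmark sets must have the same K")
    configs = []
    for s in sets:
        centered, size = _center_and_size(s.points)
        if size == 0:
            raise ValidationError(
                f"degenerate landmark set {s.leaf_id!r}: all points identical"
            )
        configs.append(centered / size if remove_scale else centered)
    X = np.stack(configs)  # (n, K, 2)

    mean = X[0].copy()
    mean, msize = _center_and_size(mean)
    mean /= msize
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean, msize = _center_and_size(new_mean)
        if msize == 0:
            raise ValidationError("mean shape collapsed to a point")
        new_mean /= msize
        change = float(np.sqrt(np.mean((new_mean - mean) ** 2)))
        mean = new_mean
        if change < tol:
            converged = True
            break
    # final superimposition onto the converged mean
    for i in range(len(X)):
        X[i] = X[i] @ _optimal_rotation(X[i], mean)
    shifts = np.linalg.norm(X - mean[None], axis=2)
    return ProcrustesResult(
        aligned_sets=X,
        mean_shape=mean,
        shift_distances=shifts,
        leaf_ids=[s.leaf_id for s in sets],
        n_iterations=it,
        converged=converged,
    )


def shift_distance_matrix(result: ProcrustesResult) -> np.ndarray:
    """(leaves x K) matrix of aligned-landmark distances to the mean shape."""
    return result.shift_distances.copy()


def landmarks_to_frame(sets: Sequence[LandmarkSet]) -> pd.DataFrame:
    """Long-format table (leaf_id, k, x, y), k 1-based."""
    frames = []
    for s in sets:
        frames.append(
            pd.DataFrame(
                {
                    "leaf_id": s.leaf_id,
                    "k": np.arange(1, s.k + 1),
                    "x": s.points[:, 0],
                    "y": s.points[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def landmarks_from_frame(df: pd.DataFrame) -> list[LandmarkSet]:
    """Inverse of :func:`landmarks_to_frame`; rows sorted by (leaf_id, k)."""
    for col in ("leaf_id", "k", "x", "y"):
        if col not in df.columns:
            raise ValidationError(f"landmark table is missing column {col!r}")
    out = []
    for leaf_id, grp in df.groupby("leaf_id", sort=False):
        grp = grp.sort_values("k")
        out.append(LandmarkSet(leaf_id=str(leaf_id), points=grp[["x", "y"]].to_numpy()))
    return out
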