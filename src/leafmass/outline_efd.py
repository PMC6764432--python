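"""Boundary tracing, Freeman chain codes and elliptical Fourier descriptors.

A closed pixel contour is traced from the binary mask (Moore-neighbor
tracing), encoded as an 8-direction Freeman chain code, and fitted with
a truncated elliptical Fourier series.  Each harmonic n contributes four
coefficients (a_n, b_n, c_n, d_n):

    x(t) = A0 + sum_n  a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = C0 + sum_n  c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

with t the arc length along the chain and T its perimeter.  The
coefficients are computed in closed form for the piecewise-linear
contour (the chain-code formulation of Kuhl-Giardina type), so the fit
is exact in the limit of many harmonics.

Normalization standardizes start point and rotation via the first
harmonic's ellipse, drops the center terms, and scales so the
first-harmonic semi-major magnitude is 1/2 (full major-axis extent 1,
i.e. unit normalized height for elongated leaves).  Reflection is
deliberately NOT removed: mirror-image leaves keep distinct
coefficients, so chirality remains available as signal (e.g. for
asymmetry studies).

Exported outline coordinates use math convention: x right, y up, origin
at the outline center; image rows are flipped once at the raster ->
contour interface and never again.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .segmentation import LeafMask

#: semi-major magnitude of the first harmonic after normalization; the
#: first-harmonic ellipse then has major-axis extent (height) 1.
NORM_SEMI_MAJOR = 0.5

# Freeman 8-direction displacements in math convention (x right, y up):
# code 0 = +x, increasing counter-clockwise.
_FREEMAN = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=int,
)
_CODE_OF = {tuple(v): k for k, v in enumerate(_FREEMAN)}


@dataclass
class Contour:
    """Closed, ordered 8-connected boundary pixel sequence.

    Points are (x=col, y=row) image coordinates; consecutive points
    (including last -> first) are 8-adjacent.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("contour points must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValidationError("contour needs at least 3 points")
        diffs = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        if np.abs(diffs).max() > 1:
            bad = int(np.argmax(np.abs(diffs).max(axis=1) > 1))
            raise ValidationError(
                f"contour points at index {bad} and {bad + 1} are not 8-adjacent"
            )

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_float_polygon(cls, points: np.ndarray) -> "Contour":
        """Wrap a real-valued closed polygon, skipping the 8-adjacency check.

        Used for analytic outlines (e.g. synthetic ground truth) that
        share the Contour interface but are not pixel chains.
        """
        obj = cls.__new__(cls)
        obj.points = np.asarray(points, dtype=float)
        if obj.points.ndim != 2 or obj.points.shape[1] != 2 or len(obj.points) < 3:
            raise ValidationError("polygon must be an (n>=3, 2) array")
        return obj


@dataclass
class ChainCode:
    """Freeman chain code: start pixel plus a closed direction sequence."""

    start: tuple[float, float]  # (x, y) in math convention (y up)
    codes: np.ndarray  # values in {0..7}

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.size == 0:
            raise ValidationError("chain code is empty")
        if self.codes.min() < 0 or self.codes.max() > 7:
            raise ValidationError("chain codes must lie in 0..7")
        disp = _FREEMAN[self.codes].sum(axis=0)
        if disp[0] != 0 or disp[1] != 0:
            raise ValidationError(
                f"chain code is not closed (net displacement {tuple(disp)})"
            )

    def to_points(self) -> np.ndarray:
        """Vertex sequence (closed; first point repeated at the end)."""
        steps = _FREEMAN[self.codes]
        pts = np.vstack([[0, 0], np.cumsum(steps, axis=0)]).astype(float)
        return pts + np.asarray(self.start, dtype=float)


@dataclass
class EFDSet:
    """Elliptical Fourier coefficients for one outline.

    ``coefficients`` is an (N, 4) array of rows (a_n, b_n, c_n, d_n);
    ``offset`` holds the center terms (A0, C0).
    """

    n_harmonics: int
    coefficients: np.ndarray
    offset: tuple[float, float]
    normalized: bool = False
    leaf_id: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.n_harmonics < 1:
            raise ValidationError("n_harmonics must be >= 1")
        if self.coefficients.shape != (self.n_harmonics, 4):
            raise ValidationError(
                f"coefficient table must be ({self.n_harmonics}, 4), "
                f"got {self.coefficients.shape}"
            )

    def to_frame(self) -> pd.DataFrame:
        n = np.arange(1, self.n_harmonics + 1)
        return pd.DataFrame(
            {
                "leaf_id": self.leaf_id,
                "n": n,
                "a": self.coefficients[:, 0],
                "b": self.coefficients[:, 1],
                "c": self.coefficients[:, 2],
                "d": self.coefficients[:, 3],
            }
        )


# ---------------------------------------------------------------------------
# boundary tracing
# ---------------------------------------------------------------------------

# Moore neighborhood in clockwise order (display sense, y down),
# starting west: W, NW, N, NE, E, SE, S, SW as (dr, dc).
_MOORE_CW = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(leaf: LeafMask | np.ndarray) -> Contour:
    """Moore-neighbor boundary trace of a single-component mask.

    Starts at the topmost-then-leftmost foreground pixel and walks the
    outer boundary clockwise (in image/display coordinates), returning
    the closed ordered contour of boundary pixels.  The foreground must
    not touch the image border (pad upstream) and must have at least
    4 pixels.
    """
    mask = leaf.mask if isinstance(leaf, LeafMask) else np.asarray(leaf, dtype=bool)
    if mask.sum() < 4:
        raise ValidationError("mask must contain at least 4 foreground pixels")
    if (
        mask[0, :].any()
        or mask[-1, :].any()
        or mask[:, 0].any()
        or mask[:, -1].any()
    ):
        raise ValidationError(
            "foreground touches the image border; pad the mask before tracing"
        )
    rows, cols = np.nonzero(mask)
    i0 = np.lexsort((cols, rows))[0]
    start = (int(rows[i0]), int(cols[i0]))

    contour = [start]
    # the start pixel's west neighbor is background by construction and
    # serves as the initial backtrack position.
    cur = start
    backtrack = (start[0], start[1] - 1)
    first_move: tuple[tuple[int, int], tuple[int, int]] | None = None
    max_steps = 4 * mask.size
    for _ in range(max_steps):
        dr, dc = backtrack[0] - cur[0], backtrack[1] - cur[1]
        k0 = _MOORE_CW.index((dr, dc))
        nxt = None
        for j in range(1, 9):
            dr, dc = _MOORE_CW[(k0 + j) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if mask[cand]:
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # single isolated pixel; rejected above but be safe
            break
        move = (cur, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            # Jacob's criterion: leaving start the same way a second time
            break
        cur = nxt
        contour.append(cur)
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    pts = np.array([(c, r) for r, c in contour])  # (x=col, y=row)
    return Contour(points=pts)


def contour_to_chain_code(contour: Contour) -> ChainCode:
    """Encode a contour as a Freeman chain code in math convention.

    Image rows are flipped here (y_math = -row) so that code 0 means
    +x (right) and codes increase counter-clockwise with y up.  This is
    the single raster -> math interface for all outline exports.
    """
    pts = contour.points.astype(float)
    math_pts = np.column_stack([pts[:, 0], -pts[:, 1]])
    closed = np.vstack([math_pts, math_pts[:1]])
    diffs = np.diff(closed, axis=0).astype(int)
    codes = []
    for i, (dx, dy) in enumerate(diffs):
        key = (int(dx), int(dy))
        if key not in _CODE_OF:
            raise ValidationError(
                f"contour points {i} and {i + 1} are not 8-adjacent (step {key})"
            )
        codes.append(_CODE_OF[key])
    return ChainCode(start=(float(math_pts[0, 0]), float(math_pts[0, 1])), codes=codes)


# ---------------------------------------------------------------------------
# elliptical Fourier fitting
# ---------------------------------------------------------------------------


def _efd_from_closed_points(pts: np.ndarray, n_harmonics: int) -> EFDSet:
    """Exact EFD of the closed piecewise-linear curve through ``pts``.

    ``pts`` need not repeat the first point; closure is implied.
    """
    pts = np.asarray(pts, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)  # (P, 2) segment steps
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    if len(dt) < 2:
        raise ValidationError("degenerate contour: fewer than 2 distinct points")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    n = np.arange(1, n_harmonics + 1)[:, None]  # (N, 1)
    phi = 2.0 * np.pi * n * t[None, :] / T  # (N, P+1)
    dcos = np.cos(phi[:, 1:]) - np.cos(phi[:, :-1])
    dsin = np.sin(phi[:, 1:]) - np.sin(phi[:, :-1])
    coef = T / (2.0 * np.pi**2 * n**2)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = (coef * (vx[None, :] * dcos)).sum(axis=1)
    b = (coef * (vx[None, :] * dsin)).sum(axis=1)
    c = (coef * (vy[None, :] * dcos)).sum(axis=1)
    dd = (coef * (vy[None, :] * dsin)).sum(axis=1)
    # center terms: exact arc-length average of the piecewise-linear curve
    mid = (closed[:-1][keep] + closed[1:][keep]) / 2.0
    A0 = float((mid[:, 0] * dt).sum() / T)
    C0 = float((mid[:, 1] * dt).sum() / T)
    return EFDSet(
        n_harmonics=n_harmonics,
        coefficients=np.column_stack([a, b, c, dd]),
        offset=(A0, C0),
        normalized=False,
    )


def efd_fit(chain: ChainCode, n_harmonics: int, leaf_id: str = "") -> EFDSet:
    """Fit N harmonics to the contour described by a chain code.

    Unit steps have arc length 1 and diagonal steps sqrt(2); the series
    is evaluated in closed form over the polygonal chain.
    """
    if n_harmonics < 1:
        raise ValidationError("n_harmonics must be >= 1")
    efd = _efd_from_closed_points(chain.to_points(), n_harmonics)
    return replace(efd, leaf_id=leaf_id)


def efd_fit_points(
    points: Sequence[Sequence[float]], n_harmonics: int, leaf_id: str = ""
) -> EFDSet:
    """Fit N harmonics directly to a closed float polygon (math convention)."""
    if n_harmonics < 1:
        raise ValidationError("n_harmonics must be >= 1")
    efd = _efd_from_closed_points(np.asarray(points, dtype=float), n_harmonics)
    return replace(efd, leaf_id=leaf_id)


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def normalize_efd(efd: EFDSet) -> EFDSet:
    """Standardize start point, rotation and size; drop the center terms.

    Start-point phase and spatial rotation are fixed by the first
    harmonic's ellipse (semi-major axis along +x); size is divided so
    the first-harmonic semi-major magnitude equals 1/2 (major-axis
    extent of the fundamental ellipse = 1).  The residual 180-degree
    ambiguity of the standardization (start shifted half a period plus
    a half-turn rotation, which negates every even harmonic) is resolved
    by requiring the first even-harmonic coefficient of significant
    magnitude to be positive.  Reflection is not removed.
    """
    if efd.normalized:
        return efd
    C = efd.coefficients.copy()
    a1, b1, c1, d1 = C[0]
    if np.hypot(a1, c1) < 1e-12 and np.hypot(b1, d1) < 1e-12:
        raise ValidationError("degenerate first harmonic; cannot normalize")
    # start-point phase of the semi-major axis
    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 - b1**2 + c1**2 - d1**2
    )
    N = efd.n_harmonics
    out = np.empty_like(C)
    for i in range(N):
        M = C[i].reshape(2, 2) @ _rot((i + 1) * theta)
        out[i] = M.ravel()
    # spatial rotation: put the (now phase-aligned) semi-major axis on +x
    psi = np.arctan2(out[0, 2], out[0, 0])
    R = _rot(-psi)
    for i in range(N):
        out[i] = (R @ out[i].reshape(2, 2)).ravel()
    semi_major = abs(out[0, 0])
    if semi_major < 1e-12:
        raise ValidationError("degenerate first harmonic; cannot normalize")
    out *= NORM_SEMI_MAJOR / semi_major
    # canonicalize the residual 180-degree ambiguity via even harmonics
    even = out[1::2].ravel()
    sig = even[np.abs(even) > 1e-9]
    if sig.size and sig[0] < 0:
        out[1::2] *= -1.0
    return EFDSet(
        n_harmonics=N,
        coefficients=out,
        offset=(0.0, 0.0),
        normalized=True,
        leaf_id=efd.leaf_id,
    )


def reconstruct_outline(efd: EFDSet, n_points: int = 256) -> np.ndarray:
    """Evaluate the truncated series at ``n_points`` uniform parameters.

    Returns an (n_points, 2) closed polyline (last point != first; the
    curve closes implicitly).
    """
    if n_points < 3:
        raise ValidationError("n_points must be >= 3")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, efd.n_harmonics + 1)[:, None]
    ang = 2.0 * np.pi * n * t[None, :]
    cos, sin = np.cos(ang), np.sin(ang)
    a, b, c, d = efd.coefficients.T
    x = efd.offset[0] + (a[:, None] * cos + b[:, None] * sin).sum(axis=0)
    y = efd.offset[1] + (c[:, None] * cos + d[:, None] * sin).sum(axis=0)
    return np.column_stack([x, y])


def mean_outline(
    efds: Sequence[EFDSet], n_points: int = 256, require_normalized: bool = True
) -> np.ndarray:
    """Reconstruct the coefficient-wise mean outline of a population.

    By linearity of the series this equals the pointwise mean of the
    individual reconstructions at shared parameter values.
    """
    if not efds:
        raise ValidationError("need at least one EFDSet")
    N = efds[0].n_harmonics
    for e in efds:
        if e.n_harmonics != N:
            raise ValidationError("all EFDSets must share the same n_harmonics")
        if require_normalized and not e.normalized:
            raise ValidationError("mean_outline requires normalized EFDSets")
    mean_coef = np.mean([e.coefficients for e in efds], axis=0)
    mean_off = tuple(np.mean([e.offset for e in efds], axis=0))
    mean_efd = EFDSet(
        n_harmonics=N,
        coefficients=mean_coef,
        offset=mean_off,
        normalized=efds[0].normalized,
        leaf_id="mean",
    )
    return reconstruct_outline(mean_efd, n_points)


def mean_efd(efds: Sequence[EFDSet]) -> EFDSet:
    """Coefficient-wise mean EFDSet of a normalized population."""
    if not efds:
        raise ValidationError("need at least one EFDSet")
    N = efds[0].n_harmonics
    if any(e.n_harmonics != N for e in efds):
        raise ValidationError("all EFDSets must share the same n_harmonics")
    if any(not e.normalized for e in efds):
        raise ValidationError("mean_efd requires normalized EFDSets")
    return EFDSet(
        n_harmonics=N,
        coefficients=np.mean([e.coefficients for e in efds], axis=0),
        offset=(0.0, 0.0),
        normalized=True,
        leaf_id="mean",
    )


def efd_feature_matrix(efds: Sequence[EFDSet]) -> np.ndarray:
    """(leaves x 4N) matrix, columns a1,b1,c1,d1,...,aN,bN,cN,dN."""
    if not efds:
        raise ValidationError("need at least one EFDSet")
    N = efds[0].n_harmonics
    for e in efds:
        if e.n_harmonics != N:
            raise ValidationError("inconsistent n_harmonics across leaves")
        if not e.normalized:
            raise ValidationError("feature matrix requires normalized EFDSets")
    return np.vstack([e.coefficients.ravel() for e in efds])
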