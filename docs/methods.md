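# Methods

This note documents the models, conventions and numerical choices behind
`leafmass`, the assumptions they rest on, and what the synthetic-fixture
tests do and do not demonstrate about real leaf images.

## Coordinate conventions

Raster coordinates are `(x = column, y = row)`, 0-based, y increasing
downward. All exported outlines and chain codes use math convention —
x right, y up — with image rows flipped exactly once, at the raster →
contour interface. Annotation polygons and landmarks are authored in
raster pixel coordinates; landmark exports are scaled to cm.

## Calibration and segmentation

The physical scale is `known_length / ‖p2 − p1‖` (cm per pixel) from two
ruler points; one calibration serves every leaf in the image. Regions
are selected by user-authored polygons (even-odd rule, boundary pixels
inside); pixels outside the polygon are filled white so a light scanner
background reads as exterior. Automatic leaf detection is deliberately
out of scope — the polygon is where the annotator excludes petioles and
stray matter.

Binarization uses Otsu's method on in-region pixels (the dark class is
`intensity ≤ t`), with a fixed-threshold override for difficult images.
Holes are filled and, if the threshold fragments the leaf, only the
largest connected component is kept, with a warning — fragmentation is
an annotation problem, not something the pipeline should silently paper
over. The result must be a single connected mask.

**Assumption:** leaves are imaged on a contrasting background with a
roughly bimodal intensity histogram. Shadows, background gradients and
overlapping leaves are not corrected.

## Orientation

The centroid and principal axes come from the 2×2 second-central-moment
matrix of foreground pixel coordinates. The axis angle is reported
relative to vertical in (−90°, 90°]; shapes with a major/minor
eigenvalue ratio below 1.02 are treated as isotropic (angle undefined,
no rotation, warning). Alignment rotates the mask about its centroid by
the negated angle (plus 90° for `width_major` leaves) with
nearest-neighbor interpolation — the mask stays binary, no
re-thresholding artifacts — and iterates measure-rotate (≤5 rounds)
until the residual is below 0.5°, since a single raster rotation is not
exact. Foreground count is conserved to well within 2%.

The 180° ambiguity of a principal axis is left unresolved: a leaf and
its upside-down copy are both "aligned". Downstream EFD normalization
and Procrustes are responsible for rotation-invariant comparison.

## Measurements and fluctuating asymmetry

Length and width are the inclusive pixel extents of the upright leaf's
bounding box times the scale; area is the foreground count times the
scale squared. Under `width_major` the horizontal extent is reported as
length.

Fluctuating asymmetry per raster row is `FA = 2(WL − WR)/(WL + WR)`,
where WL and WR are the distances from the vertical line through the
foreground centroid to the leftmost and rightmost margin pixels of the
row (interior holes were filled upstream). FA is width-normalized, 0 for
a symmetric row, positive when the row skews left. Rows lying entirely
on one side of the axis have the off-side distance clamped to zero,
giving FA = ±2; they are included in the per-leaf mean of |FA| because
excluding them would hide extreme asymmetry. Single-pixel rows (zero
total width) are excluded. Rows are evaluated at every raster line.

One consequence of the centroid-axis choice is worth stating: the
centroid x is the width-weighted mean of row midpoints, so no shape can
have WL > WR on literally every row — a leaf bulging left necessarily
has narrow rows (typically at the tips) scoring negative. The sign
convention is therefore verified on rows, where it is exact, not on
whole-shape aggregates.

## Elliptical Fourier descriptors

Boundary tracing is Moore-neighbor with Jacob's stopping criterion,
starting at the topmost-then-leftmost foreground pixel, clockwise in
display coordinates; the foreground must not touch the image border
(the pipeline pads by 2 px before tracing). The traced contour becomes a
Freeman chain code (code 0 = +x, counter-clockwise in math convention).

The elliptical Fourier coefficients of the chain's polygon are computed
in closed form for a piecewise-linear curve parameterized by arc length
(unit steps contribute Δt = 1, diagonal steps √2); the center terms
(A0, C0) are the exact arc-length average. Four coefficients per
harmonic; N = 15 by default (60 parameters per outline), configurable —
15–20 harmonics capture typical leaf outlines, and the residual RMS
error decreases monotonically in N by Parseval's identity.

Normalization: the start-point phase and spatial rotation are
standardized via the first harmonic's ellipse, the center terms are
dropped, and size is divided so the first-harmonic semi-major magnitude
is 0.5 — the fundamental ellipse then has unit major-axis extent, which
approximates unit outline height for elongated leaves. The standard
phase/rotation fix leaves a residual 180° ambiguity (start shifted half
a period plus a half-turn, which negates every even harmonic); it is
canonicalized by requiring the first even-harmonic coefficient of
magnitude above 1e-9 to be positive. For shapes with no even-harmonic
energy (ellipses) the ambiguity is vacuous. Reflection is deliberately
**not** normalized away: mirror-image leaves occupy distinct positions
in coefficient space, keeping chirality available as signal for
asymmetry studies.

On float contours the normalized coefficients are invariant to
translation, rotation, scaling and start shifts to machine precision;
after re-rasterization of a rotated/rescaled leaf they agree to a few
thousandths of the normalized height (raster noise), comfortably within
the 2% documented tolerance.

Mean outlines are coefficient-wise means of normalized sets, which by
linearity equal pointwise means of reconstructions at shared parameter
values (exactly; asserted to 1e-12).

## Landmarks and generalized Procrustes analysis

Landmarks are ordered points; the order is the homology correspondence
and must be planned consistently across a study. GPA removes translation
(centroids to the origin), size (centroid size — the root summed squared
landmark distance from the centroid — to 1; `--no-scaling` keeps size),
and rotation (least-squares orthogonal fit via SVD with the determinant
corrected so reflections are never used). The mean shape is re-estimated
and re-normalized until its RMS change is below 1e-10 (≤100 iterations).
Shift distances — per-landmark Euclidean distances from each aligned
specimen to the mean landmark — are the default PCA feature space
(K columns); aligned coordinates (2K columns) are also exported.

## PCA and t-tests

PCA is column-mean-centered without variance scaling (normalized EFD
coefficients share a scale; `--scale` switches to correlation PCA),
computed by full SVD. Sign is fixed deterministically: the
largest-magnitude loading of each component is positive. Explained
fractions over all components sum to 1; zero-variance input yields
all-zero scores with a warning rather than an error. Group comparisons
use Welch's unequal-variance t-test; the one-tailed p-value is half the
two-tailed one in the observed direction.

## Synthetic leaf generator

The generator emulates pressed-leaf silhouettes with a polar outline
about the origin, φ measured from the apex:

    r(φ) = r_ellipse(φ) · (1 + lobe_depth · cos(n_lobes φ))
                        · (1 − skew · sin φ) · (1 + noise(φ))

The ellipse base sets length and width; the cosine term adds palmate
lobes; the odd skew term widens the left side for positive skew; noise
is a seeded sum of five random low-order harmonics. Star-shaped outlines
cannot self-intersect while r > 0, and parameter combinations driving
r toward zero are rejected. Rasterization is analytic — a pixel is
foreground iff its radius at its angle (in the unrotated frame) is
within the interpolated outline radius — which keeps the mask exactly
mirror-symmetric when skew = 0 and the rotation is a multiple of 180°,
so the symmetric-leaf FA test asserts against an exact zero rather than
rasterization noise.

Ground truth (length, width, area, mean |FA| via exact scanline
intersections of the dense polygon, and landmark positions at the 2n
lobe-modulation extrema: n tips including the apex alternating with n
sinuses including the base) comes from the analytic outline, never from
the raster, so generator and pipeline cannot share an error. Default
dimensions (~200 px long) put rasterization error near 1% of extent;
populations jitter parameters with per-field Gaussian spreads behind a
single seed.

**What the fixtures do not show:** real scans have uneven illumination,
petioles, damaged margins, overlapping laminae and ruler markings; the
generator produces none of these. Passing tests demonstrate the
correctness of the geometry and statistics, not robustness to imaging
artifacts — that remains the annotator's polygon and the threshold
override.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses: one lobed leaf (N = 15) for the
coefficient count; a 720-point float contour for invariances and
truncation; ~200 px leaves rotated 37° / scaled 2.5× for raster
invariance; a 23-landmark template with 20 specimens for exact GPA
recovery and 500 replicates of 20 specimens at noise σ = 0.02 for noisy
recovery (reported relative to the 3σ/√n bound); 2000 samples of a
rotated (9, 1)-variance Gaussian for PCA calibration; 10 000 replicate
equal-mean t-tests (n = 15 per arm) for the type-I error rate; a grid of
three analytic fixtures for measurement accuracy; and two 15-leaf
populations (lobed vs entire) for end-to-end EFD-PCA separation,
reported in pooled standard deviations on PC1.

## Known limitations

- Chain-code EFDs inherit raster quantization; sub-pixel outline methods
  would reduce the ~0.5% coefficient noise but are out of scope.
- The FA axis is the centroid vertical; a midrib-based axis would differ
  on strongly curved leaves.
- Largest-component retention after thresholding can silently discard a
  genuinely split lamina (it warns, but proceeds).
- No semi-landmarks, bending-energy visualization, CVA/MANOVA or
  allometric regression; PCA and t-tests are the only statistics.
- Perimeter, circularity and lobe counting are not measured.
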