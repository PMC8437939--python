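# Methods

This note documents the measurement model, the numerical choices, and the
limits of what the synthetic experiments can show.

## Measurement substrate

Images are 512 × 512 boolean rasters with one 8-connected foreground
component (the AOI). Coordinates: x = column (rightward), y = row
(downward); angles are counterclockwise from +x in the mathematical sense
applied to (x, −y). Reference shapes are rasterized with a horizontal
extent of 97 px, centered by centroid on the canvas center, as an apex-up
equilateral triangle, a square, a regular apex-up pentagon, a regular
flat-top hexagon, and a circle; a pixel is foreground when its center
lies inside the continuous shape.

**Radial profile.** d(θ) is estimated per whole degree as the largest
centroid distance of any foreground pixel in the 1° wedge around θ,
followed by a circular ±1-wedge maximum. The rolling maximum is needed
because beyond ≈ 29 px radius a pixel's angular footprint exceeds one
wedge, so rim pixels can straddle wedge boundaries and leave a wedge
without its outermost sample (up to ~7 px undershoot on flat axis-aligned
edges without the correction). The residual error against a dense
0.25-px ray march is below 1.5 px for the pentagon and hexagon and below
2.5 px for the triangle, whose profile slope near its 60° vertices is the
steepest (d′(θ) ≈ d·tan of the edge angle). For concave regions a ray may
cross the boundary several times; the outermost crossing is used, and a
profile whose centroid falls outside the AOI is flagged rather than
rejected.

**Matching.** The input's bounding box is rescaled anisotropically onto
*each* reference's own box before profiling, so pure elongation is
invisible to identification by construction. RMSD uses 360 samples
(θ = 0…359; a closed 0…360 sum would double-count the seam). Ties are
broken in the fixed order triangle, rectangle, pentagon, hexagon, circle.
AOIs under 50 px are rejected as degenerate.

## Alignment

* **EEM** rotates by minus the signed equivalent-ellipse angle only. It is
  deliberately left blind to 180° flips and is flagged degenerate when
  minor/major > 0.98 (no defined axis); both failure modes are inherent
  to the method and are part of what the benchmark measures.
* **Extrema** forms up to four candidate rotations from the lines joining
  consecutive extreme boundary points clockwise (top-right → right-top,
  right-bottom → bottom-right, …); a coincident pair (an axis-aligned box
  corner) contributes the null rotation. Candidates are rounded to whole
  degrees and scored by the minimum per-reference RMSD after box
  normalization; the tie-break prefers the smaller angle.
* **Manual** scans all 360 whole-degree rotations with the same score,
  ties to the smallest angle. Because the extrema candidates lie on the
  same grid, manual's objective is never worse — the basis of the
  alignment-quality ordering test.

Candidate scoring rotates foreground pixel *coordinates* instead of
resampling the image (an order of magnitude faster, sub-pixel equivalent);
the returned aligned image is produced by a real order-0 rotation at the
chosen angle. Order-0 (nearest-neighbor) resampling with re-binarization
is used for every geometric transform, reproducing the zigzag boundary
artefact characteristic of hard re-binarization.

## Deformation engine

Affine deformations are the scaling matrices diag(S, S), diag(S, 1),
diag(1, S) about the image center. The convexity/concavity warp is driven
by the cubic radial law ρ + ρ³·S/max(d)² about the AOI centroid:

* **convex** applies the law as an *inverse* mapping (the resampling
  convention of MATLAB-style `imwarp` pipelines): high-radius directions
  are blunted, the shape becomes rounder and more circle-like, and
  Extent_Ellipse rises (l > 100);
* **concave** applies it as a *forward* mapping: high-radius directions
  are accentuated, the sides between them appear caved-in, and
  Extent_Ellipse falls (l < 100). The forward form is first-order
  equivalent to the inverse of the subtractive law but remains well-posed
  at every S (the literal inverse is only solvable for S ≤ 4/27 and
  produces fold-over beyond it).

The warped boundary is refilled as a 720-vertex polygon (with a half-pixel
radial allowance so the refill reproduces the pixel coverage of the
marched boundary) and, by default, renormalized anisotropically to the
input bounding box. This isolates the change of *shape* from the change
of size: j and k are exactly invariant under a pure warp, matching the
(0, 0, 0, ±, 1) pattern taxonomy. Exact invariance of i, j and k
simultaneously is geometrically impossible — blunting a triangle's
corners at a fixed box must change its area — so i carries a bounded
residual (≤ ~10 % for the triangle at S = 0.35, ≈ 0 for near-elliptical
shapes). Isotropic area renormalization and the raw remap are available
as alternatives (`preserve="area" | "none"`); the raw radial remap moves
the centroid by < 0.2 px.

**Descriptor sensitivity ceiling.** l can only rise as far as the
elliptical ceiling Extent_Ellipse = 1. The undeformed hexagon (0.992) and
circle (1.000) sit essentially at that ceiling, so convexity is expressed
in l by at most ~0.8 points for the hexagon and not at all for the circle
(a radially warped circle is still a circle). The separability and
m-flip tests therefore use the triangle and the square, whose baselines
(0.83, 0.95) leave room; this is a property of the descriptor, not of the
implementation.

## Corpus generator

The corpus design spans 12 pattern codes with counts 120 (undeformed),
240 per single deformation and 480 per combined deformation (4200 total),
split equally over the five shapes, each image at a uniformly random
orientation. Published magnitude distributions do not exist, so defaults
were chosen once as "visible but non-degenerate": affine factors uniform
on [0.6, 0.9] ∪ [1.1, 1.4], warp S uniform on [0.05, 0.35]. Composition
order is fixed: swelling → horizontal → vertical elongation → warp →
rotation. Generation is bit-reproducible from (config, master seed).

Because the magnitudes are a choice, absolute benchmark accuracies are
not comparable to any external figure; what the tests assert instead are
the *orderings and invariances* that survive any reasonable magnitude
choice: manual ≥ extrema ≥ EEM ≥ none (row-mean accuracy), perfect
identification of undeformed shapes under extrema alignment, and the
descriptor separability suite. Synthetic images also lack everything real
photographs have — illumination gradients, segmentation noise, partial
occlusion, non-polygonal outlines — so passing tests demonstrate the
geometry pipeline, not robustness to acquisition conditions.

## Uniformity classification

α_u = (j − k)/min(j, k) × 100 is computed on the *ratio* (index) scale,
not on fractional changes: only this reading reproduces the published
uniform/non-uniform labels of the drying-experiment table that the
thresholds were calibrated against (a fractional reading mislabels, e.g.,
a frame with j = 86.6, k = 84.8, l = 100.04 as non-uniform). Deformation
is uniform only when |α_u| < 5 % *and* |l − 100| < 1 %. If a box ratio is
numerically zero α_u is undefined and m falls back to the l criterion
alone.

## Baselines

Extent = A/A_BB. Box counting uses grid-anchored boxes of sizes
{2, 4, 8, 16, 32} px on the 512 canvas ("intercepted" = contains ≥ 1
foreground pixel — filled-region counting, required for D_F → 2 on large
AOIs) and fits the least-squares slope of log N_r vs log(1/r). The sweep
is capped at 32 px because with coarser boxes the counts of mid-sized
centered objects saturate at the four cells meeting at the image center
and the slope no longer reflects filled-region scaling; with this
schedule the three regimes emerge: D_F near 1 for point-like AOIs, ≈ 1.86
for rectangles filling 5–20 % of the canvas, ≥ 1.9 above 20 %. The
rule-classifier ranges are not published; the defaults are calibrated
once so the three canonical rasterized shapes self-classify
(rectangularity windows 0.52–0.70 / 0.95–1.15 / 0.72–0.86 with RAR and
FMR guards) and live in an overridable mapping. Reproducing the original
rule set exactly would require its source publication.

## Problem sizes

Default test and acceptance runs use reduced problem sizes chosen as the
smallest that exercise every code path with stable statistics: a
90-image corpus (12 patterns × 5 shapes) for the alignment-ordering
benchmark, 120 orientations for the undeformed-identification check,
6-point size sweeps for Extent and 12–20 seeded draws for the fractal
band. All are package-level choices; the full 4200-image design is
available via `default_config()`.

## Known limitations

* Single-object scenes only; no 3-D analysis, color or texture.
* The extrema method's candidate set assumes reasonably polygonal
  outlines; heavily convexed shapes can move their extreme points onto
  the bulges (reflected in lower benchmark accuracy for convex patterns,
  not worked around).
* Wedge-based profiles carry ±1–2.5 px noise depending on local boundary
  slope; identification margins (several px RMSD between references) are
  comfortably larger, but descriptors of objects much smaller than ~50 px
  would be quantization-dominated.
* The uniformity thresholds (5 %, 1 %) are adopted as published
  calibration constants, not re-derived.
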