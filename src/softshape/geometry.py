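"""Reference-shape rasterization, region properties and radial contour profiles.

This module is the measurement substrate shared by the whole package.  A
*binary image* is a 2-D boolean :class:`numpy.ndarray` whose ``True`` pixels
form the area of interest (AOI).  Conventions, fixed once for
reproducibility:

* arrays are indexed ``[row, col]``; ``x`` is the column axis (rightward)
  and ``y`` the row axis (downward);
* angles are measured counterclockwise from the +x axis in the usual
  mathematical sense applied to ``(x, -y)``, i.e. on screen a positive
  angle turns toward the top of the image;
* the radial profile samples the 360 whole-degree directions
  ``theta = 0 .. 359`` and records, for each ray from the centroid, the
  distance to the *outermost* foreground crossing (stable for mildly
  concave regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

__all__ = [
    "SHAPE_NAMES",
    "RegionProps",
    "RadialProfile",
    "ReferenceShape",
    "rasterize_reference",
    "reference_set",
    "region_props",
    "radial_profile",
    "profile_from_points",
    "rmsd",
]

#: The five reference geometric shapes, in canonical (tie-break) order.
SHAPE_NAMES = ("triangle", "rectangle", "pentagon", "hexagon", "circle")

N_THETA = 360


# ---------------------------------------------------------------------------
# region properties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionProps:
    """Geometric properties of the single foreground component (AOI).

    Attributes
    ----------
    area:
        Foreground pixel count ``A`` (px^2).
    centroid:
        ``(x, y)`` centroid in pixel coordinates (x = column, y = row).
    bbox_length, bbox_width:
        Horizontal extent ``L`` and vertical extent ``W`` of the
        axis-aligned bounding box (px).
    major, minor:
        Axis lengths of the ellipse with the same normalized second
        central moments as the AOI (px).
    alpha_ellipse:
        Acute angle between the equivalent-ellipse major axis and the
        horizontal axis, in degrees (0..90).
    theta_ellipse:
        Signed major-axis angle in degrees, in ``(-90, 90]``; positive
        turns counterclockwise (y up).  ``0`` for degenerate (isotropic)
        regions.
    extrema:
        The 8 extreme boundary points as ``(x, y)`` pairs in the order
        top-left, top-right, right-top, right-bottom, bottom-right,
        bottom-left, left-bottom, left-top.
    feret_max:
        Maximum Feret (caliper) diameter (px).
    """

    area: float
    centroid: tuple[float, float]
    bbox_length: int
    bbox_width: int
    major: float
    minor: float
    alpha_ellipse: float
    theta_ellipse: float
    extrema: tuple[tuple[float, float], ...]
    feret_max: float

    @property
    def bbox_area(self) -> int:
        """Area ``A_BB = L * W`` of the axis-aligned bounding box."""
        return self.bbox_length * self.bbox_width

    @property
    def extent(self) -> float:
        """``A / A_BB`` -- fill fraction of the bounding box."""
        return self.area / self.bbox_area

    @property
    def extent_ellipse(self) -> float:
        """``A / (pi/4 * major * minor)`` -- area relative to the
        equivalent-ellipse area.  1.0 for an ideal ellipse; lower for
        pointed shapes."""
        return self.area / (np.pi / 4.0 * self.major * self.minor)


def _single_component(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype != bool:
        img = img > 0
    if not img.any():
        raise ValueError("image has no foreground pixels")
    n = measure.label(img, connectivity=2).max()
    if n != 1:
        raise ValueError(f"expected exactly one foreground component, found {n}")
    return img


def _extrema_points(img: np.ndarray) -> tuple[tuple[float, float], ...]:
    """The 8 extreme boundary points, MATLAB-style ordering."""
    rows, cols = np.nonzero(img)
    rmin, rmax = rows.min(), rows.max()
    cmin, cmax = cols.min(), cols.max()

    top_cols = cols[rows == rmin]
    bottom_cols = cols[rows == rmax]
    right_rows = rows[cols == cmax]
    left_rows = rows[cols == cmin]
    return (
        (float(top_cols.min()), float(rmin)),      # top-left
        (float(top_cols.max()), float(rmin)),      # top-right
        (float(cmax), float(right_rows.min())),    # right-top
        (float(cmax), float(right_rows.max())),    # right-bottom
        (float(bottom_cols.max()), float(rmax)),   # bottom-right
        (float(bottom_cols.min()), float(rmax)),   # bottom-left
        (float(cmin), float(left_rows.max())),     # left-bottom
        (float(cmin), float(left_rows.min())),     # left-top
    )


def region_props(img: np.ndarray) -> RegionProps:
    """Measure the AOI of a single-component binary image.

    Raises ``ValueError`` if the foreground is empty or has more than one
    connected component (8-connectivity).
    """
    img = _single_component(img)
    rp = measure.regionprops(img.astype(np.uint8))[0]

    # signed major-axis angle from central moments in the (x, y-up) frame
    mu = measure.moments_central(img.astype(np.float64), order=2)
    mxx = mu[0, 2]   # var along x (columns)
    myy = mu[2, 0]   # var along y (rows)
    mxy = -mu[1, 1]  # y flipped to point up
    if np.hypot(2.0 * mxy, mxx - myy) < 1e-9 * max(mxx + myy, 1.0):
        theta = 0.0  # isotropic: orientation undefined
    else:
        theta = 0.5 * np.degrees(np.arctan2(2.0 * mxy, mxx - myy))
    if theta <= -90.0:
        theta += 180.0

    minr, minc, maxr, maxc = rp.bbox
    cy, cx = rp.centroid
    return RegionProps(
        area=float(rp.area),
        centroid=(float(cx), float(cy)),
        bbox_length=int(maxc - minc),
        bbox_width=int(maxr - minr),
        major=float(rp.axis_major_length),
        minor=float(rp.axis_minor_length),
        alpha_ellipse=float(abs(theta)),
        theta_ellipse=float(theta),
        extrema=_extrema_points(img),
        feret_max=float(rp.feret_diameter_max),
    )


# ---------------------------------------------------------------------------
# radial profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadialProfile:
    """Centroid-to-edge distances at the 360 whole-degree directions."""

    d: np.ndarray
    centroid_inside: bool = True

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (N_THETA,):
            raise ValueError(f"profile must have {N_THETA} samples, got {d.shape}")
        object.__setattr__(self, "d", d)

    @property
    def max(self) -> float:
        return float(self.d.max())


def profile_from_points(x: np.ndarray, y_up: np.ndarray) -> RadialProfile:
    """Radial profile of a point cloud about its own mean.

    ``x``/``y_up`` are foreground sample positions in a frame whose y axis
    points up.  Each 1-degree wedge records the distance of its farthest
    sample, which approximates the outermost boundary crossing of the ray
    through the wedge center.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_up, dtype=float)
    cx = x.mean()
    cy = y.mean()
    dx = x - cx
    dy = y - cy
    r = np.hypot(dx, dy)
    bins = np.rint(np.degrees(np.arctan2(dy, dx))).astype(np.int64) % N_THETA
    d = np.full(N_THETA, -1.0)
    np.maximum.at(d, bins, r)
    # each sample stands for a full pixel whose angular footprint exceeds
    # the 1-degree wedge beyond ~29 px radius, so rim pixels can straddle
    # wedge boundaries and leave a wedge without its outermost sample: a
    # circular +/-1-wedge maximum restores the outer rim (and fills the
    # occasional empty knife-edge wedge)
    d = np.maximum(d, np.maximum(np.roll(d, 1), np.roll(d, -1)))
    empty = d < 0
    if empty.any():
        idx = np.arange(N_THETA)
        d[empty] = np.interp(idx[empty], idx[~empty], d[~empty], period=N_THETA)
    return RadialProfile(d=d)


def radial_profile(img: np.ndarray) -> RadialProfile:
    """Radial profile of a binary image about the AOI centroid.

    The profile is flagged (``centroid_inside=False``) when the centroid
    pixel itself is background, which happens for extremely concave
    regions; distances are still reported.
    """
    img = _single_component(img)
    rows, cols = np.nonzero(img)
    prof = profile_from_points(cols.astype(float), -rows.astype(float))
    cy = int(round(rows.mean()))
    cx = int(round(cols.mean()))
    inside = bool(img[cy, cx])
    if inside:
        return prof
    return RadialProfile(d=prof.d, centroid_inside=False)


def rmsd(p: RadialProfile | np.ndarray, q: RadialProfile | np.ndarray) -> float:
    """Root-mean-square difference of two radial profiles.

    ``RMSD = sqrt( sum_theta (d_ref - d_img)^2 / 360 )`` over the 360
    stored samples.  Non-negative and symmetric in its arguments.
    """
    a = p.d if isinstance(p, RadialProfile) else np.asarray(p, dtype=float)
    b = q.d if isinstance(q, RadialProfile) else np.asarray(q, dtype=float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


# ---------------------------------------------------------------------------
# reference shapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceShape:
    """A rasterized reference geometry with its cached measurements."""

    name: str
    image: np.ndarray
    profile: RadialProfile
    props: RegionProps

    @property
    def bbox(self) -> tuple[int, int]:
        """(L, W) of the reference AOI bounding box."""
        return (self.props.bbox_length, self.props.bbox_width)


def _polygon_vertices(name: str, side: float) -> np.ndarray:
    """Vertices (x, y-up) of the unit reference polygon, width = ``side``.

    triangle: apex-up equilateral; rectangle: square; pentagon: regular,
    apex-up; hexagon: regular, flat-top.  Width (horizontal extent) equals
    ``side`` in every case.
    """
    if name == "triangle":
        h = side * np.sqrt(3.0) / 2.0
        return np.array([(0.0, 2 * h / 3), (side / 2, -h / 3), (-side / 2, -h / 3)])
    if name == "rectangle":
        s = side / 2.0
        return np.array([(-s, -s), (s, -s), (s, s), (-s, s)])
    if name == "pentagon":
        ang = np.radians(90 + 72 * np.arange(5))
        v = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        v *= side / (v[:, 0].max() - v[:, 0].min())
        return v
    if name == "hexagon":
        ang = np.radians(60 * np.arange(6))
        v = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        v *= side / 2.0  # flat-top: width = 2 R
        return v
    raise ValueError(f"unknown shape {name!r}; expected one of {SHAPE_NAMES}")


def rasterize_reference(name: str, side: int = 97, canvas: int = 512) -> ReferenceShape:
    """Rasterize one of the five reference geometric shapes.

    The shape is centered on a ``canvas x canvas`` background with a
    horizontal extent of ``side`` pixels.  A pixel is foreground when its
    center lies inside the continuous shape.
    """
    if name not in SHAPE_NAMES:
        raise ValueError(f"unknown shape {name!r}; expected one of {SHAPE_NAMES}")
    if not 0 < side < canvas:
        raise ValueError("side must satisfy 0 < side < canvas")
    c = (canvas - 1) / 2.0
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    x = xx - c
    y = c - yy  # y up
    if name == "circle":
        img = np.hypot(x, y) <= side / 2.0
    else:
        verts = _polygon_vertices(name, float(side))
        img = measure.points_in_poly(
            np.column_stack([x.ravel(), y.ravel()]), verts
        ).reshape(canvas, canvas)
    img = ndi.binary_fill_holes(img)
    return ReferenceShape(
        name=name, image=img, profile=radial_profile(img), props=region_props(img)
    )


_REFERENCE_CACHE: dict[tuple[int, int], tuple[ReferenceShape, ...]] = {}


def reference_set(side: int = 97, canvas: int = 512) -> tuple[ReferenceShape, ...]:
    """All five reference shapes, cached, in canonical order."""
    key = (side, canvas)
    if key not in _REFERENCE_CACHE:
        _REFERENCE_CACHE[key] = tuple(
            rasterize_reference(n, side, canvas) for n in SHAPE_NAMES
        )
    return _REFERENCE_CACHE[key]
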