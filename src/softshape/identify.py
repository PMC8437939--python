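"""Shape identification and the i, j, k, l, m deformation descriptors.

Identification: after optional alignment, the input's bounding box is
matched anisotropically to each reference's box and the radial-profile
RMSD computed against each of the five references; the label is the
reference with the lowest RMSD (fixed tie order triangle, rectangle,
pentagon, hexagon, circle).

Description: an image is compared against an undeformed baseline state
through four percent indices (100 = no change),

* ``i``  -- area ratio ``A / A_ini``,
* ``j``  -- bounding-box length ratio ``L / L_ini`` (horizontal),
* ``k``  -- bounding-box width ratio ``W / W_ini`` (vertical),
* ``l``  -- ratio of ``Extent_Ellipse = A / (pi/4 major minor)``,
  the area relative to the equivalent-ellipse area: l > 100 signals
  convexity (the shape became rounder), l < 100 concavity,

plus the uniformity statistic ``alpha_u = (j - k) / min(j, k) * 100``
and the categorical flag ``m``: deformation is *uniform* only when
``|alpha_u| < 5`` percent and ``|l - 100| < 1`` percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignmentResult, align, score_rotation, _points_xy
from .geometry import SHAPE_NAMES, RegionProps, ReferenceShape, reference_set, region_props

__all__ = [
    "ShapeMatch",
    "Descriptors",
    "ReferenceState",
    "match_shape",
    "compute_descriptors",
    "classify_uniformity",
    "reference_state",
]

#: Uniformity thresholds, in percent: |alpha_u| < 5 and |l - 100| < 1.
ALPHA_THRESHOLD = 5.0
L_THRESHOLD = 1.0

MIN_AOI_PIXELS = 50


@dataclass(frozen=True)
class ShapeMatch:
    """Identification result: best label, per-reference RMSD, alignment."""

    label: str
    rmsd_by_shape: dict[str, float]
    alignment: AlignmentResult


@dataclass(frozen=True)
class ReferenceState:
    """Baseline measurements of the undeformed comparison image."""

    area: float
    bbox_length: float
    bbox_width: float
    extent_ellipse: float

    def __post_init__(self):
        if min(self.area, self.bbox_length, self.bbox_width, self.extent_ellipse) <= 0:
            raise ValueError("reference-state fields must be positive")


@dataclass(frozen=True)
class Descriptors:
    """Deformation descriptors on the percent-index scale (100 = no change).

    ``alpha_u`` is ``None`` when undefined (a degenerate zero box
    dimension); ``m`` is then decided on ``l`` alone.  The fractional
    forms of the indices ((value - 100) / 100) are exposed as
    ``i_frac`` etc. for convenience.
    """

    i: float
    j: float
    k: float
    l: float
    alpha_u: float | None
    m: str
    extent_ellipse: float

    @property
    def i_frac(self) -> float:
        return (self.i - 100.0) / 100.0

    @property
    def j_frac(self) -> float:
        return (self.j - 100.0) / 100.0

    @property
    def k_frac(self) -> float:
        return (self.k - 100.0) / 100.0

    @property
    def l_frac(self) -> float:
        return (self.l - 100.0) / 100.0


def reference_state(img_or_props: np.ndarray | RegionProps) -> ReferenceState:
    """Baseline state from an undeformed image (or its RegionProps)."""
    p = img_or_props if isinstance(img_or_props, RegionProps) else region_props(img_or_props)
    return ReferenceState(
        area=p.area,
        bbox_length=float(p.bbox_length),
        bbox_width=float(p.bbox_width),
        extent_ellipse=p.extent_ellipse,
    )


def match_shape(
    img: np.ndarray,
    refs: tuple[ReferenceShape, ...] | None = None,
    method: str = "extrema",
) -> ShapeMatch:
    """Identify the reference shape closest to a segmented binary image.

    The image is aligned by ``method`` (``none``/``eem``/``extrema``/
    ``manual``), its bounding box matched to each reference's box, and
    the radial-profile RMSD computed; the lowest RMSD wins, ties broken
    in the canonical shape order.
    """
    refs = refs if refs is not None else reference_set()
    img = np.asarray(img)
    if img.dtype != bool:
        img = img > 0
    if img.sum() < MIN_AOI_PIXELS:
        raise ValueError(f"AOI below {MIN_AOI_PIXELS} px: too degenerate to match")
    result = align(img, method, refs)
    scores = score_rotation(_points_xy(result.aligned), 0.0, refs)
    label = min(SHAPE_NAMES, key=lambda n: (scores[n], SHAPE_NAMES.index(n)))
    return ShapeMatch(label=label, rmsd_by_shape=scores, alignment=result)


def classify_uniformity(alpha_u: float | None, l: float) -> str:
    """Uniform vs non-uniform deformation from alpha_u and l (percent).

    Uniform only when ``|alpha_u| < 5`` and ``|l - 100| < 1``; an
    undefined ``alpha_u`` leaves the decision to ``l`` alone.
    """
    if not np.isfinite(l):
        return "non-uniform"
    l_ok = abs(l - 100.0) < L_THRESHOLD
    if alpha_u is None or not np.isfinite(alpha_u):
        return "uniform" if l_ok else "non-uniform"
    return "uniform" if (abs(alpha_u) < ALPHA_THRESHOLD and l_ok) else "non-uniform"


def compute_descriptors(img: np.ndarray, ref: ReferenceState) -> Descriptors:
    """Deformation descriptors of ``img`` relative to a baseline state."""
    p = region_props(img)
    ri = p.area / ref.area
    rj = p.bbox_length / ref.bbox_length
    rk = p.bbox_width / ref.bbox_width
    rl = p.extent_ellipse / ref.extent_ellipse
    if min(rj, rk) <= 0:
        alpha_u: float | None = None
    else:
        alpha_u = (rj - rk) / min(rj, rk) * 100.0
    l = 100.0 * rl
    return Descriptors(
        i=100.0 * ri,
        j=100.0 * rj,
        k=100.0 * rk,
        l=l,
        alpha_u=alpha_u,
        m=classify_uniformity(alpha_u, l),
        extent_ellipse=p.extent_ellipse,
    )
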