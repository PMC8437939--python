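"""Segmentation and image alignment.

An arbitrarily oriented object must be rotated into a canonical pose
before radial-profile matching.  Three methods are provided, in
increasing order of cost and (typically) accuracy:

``eem``
    Equivalent-ellipse method: rotate by the angle of the ellipse with
    the AOI's normalized second central moments, until that angle is 0.
    One candidate; blind to 180-degree flips and undefined for isotropic
    shapes -- these failure modes are inherent to the method and are
    deliberately not patched.
``extrema``
    Evaluate up to four candidate rotations, one per line joining
    consecutive extreme boundary points around the object (top-right to
    right-top, right-bottom to bottom-right, ...); each candidate makes
    that line horizontal.  Candidates are scored by the best
    reference-matching RMSD and the winner returned.
``manual``
    Exhaustive scan of all 360 whole-degree rotations, scored the same
    way; the global argmin (smallest angle on ties) wins.  Because the
    extrema candidates are rounded onto the same grid, the manual
    objective can never exceed the extrema objective.

Candidate scoring rotates the foreground pixel coordinates rather than
resampling the image -- equivalent up to sub-pixel effects and an order
of magnitude faster; the returned aligned image is produced by a real
order-0 image rotation at the chosen angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure

from .geometry import (
    N_THETA,
    RadialProfile,
    ReferenceShape,
    profile_from_points,
    reference_set,
    region_props,
    rmsd,
)

__all__ = [
    "AlignmentResult",
    "segment",
    "rotate_image",
    "align_eem",
    "align_extrema",
    "align_manual",
    "align",
    "score_rotation",
]


@dataclass
class AlignmentResult:
    """Outcome of an alignment step.

    ``angle`` is the applied rotation in degrees (mod 360,
    counterclockwise with y up); ``candidates`` lists every evaluated
    ``(angle, rmsd_by_reference)`` pair (the per-reference map is empty
    for the reference-free ``eem``); ``objective`` is the winning
    min-over-references RMSD where applicable; ``degenerate`` flags
    inputs for which the method had no information (e.g. a circle under
    ``eem``).
    """

    aligned: np.ndarray
    angle: float
    method: str
    candidates: list[tuple[float, dict[str, float]]] = field(default_factory=list)
    objective: float | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment(raw: np.ndarray, canvas: int = 512) -> np.ndarray:
    """Binary AOI from a grayscale (or already binary) image.

    Otsu thresholding, border-artefact removal, largest-component
    selection and hole filling; the result is cropped or padded to a
    ``canvas x canvas`` frame (images already at the target size keep
    their geometry).
    """
    raw = np.asarray(raw)
    if raw.ndim == 3:
        raw = raw[..., :3].mean(axis=2)
    if raw.dtype == bool:
        binary = raw.copy()
    else:
        vals = raw.astype(float)
        if vals.max() == vals.min():
            raise ValueError("blank image: no foreground found")
        thr = filters.threshold_otsu(vals)
        binary = vals > thr
        # object assumed bright on dark; flip if the border is mostly "on"
        border = np.concatenate([binary[0], binary[-1], binary[:, 0], binary[:, -1]])
        if border.mean() > 0.5:
            binary = ~binary
    if not binary.any():
        raise ValueError("blank image: no foreground found")

    labels = measure.label(binary, connectivity=2)
    n = labels.max()
    if n > 1:
        # drop components touching the border unless everything does
        border_ids = set(np.unique(np.concatenate(
            [labels[0], labels[-1], labels[:, 0], labels[:, -1]]))) - {0}
        sizes = np.bincount(labels.ravel())
        keep_ids = [i for i in range(1, n + 1) if i not in border_ids]
        if not keep_ids:
            keep_ids = list(range(1, n + 1))
        best = max(keep_ids, key=lambda i: sizes[i])
        binary = labels == best
    binary = ndi.binary_fill_holes(binary)

    if binary.shape == (canvas, canvas):
        return binary
    # re-frame around the AOI center
    rows, cols = np.nonzero(binary)
    cy = int(round(rows.mean()))
    cx = int(round(cols.mean()))
    out = np.zeros((canvas, canvas), dtype=bool)
    half = canvas // 2
    for r, c in zip(rows, cols):
        rr = r - cy + half
        cc = c - cx + half
        if 0 <= rr < canvas and 0 <= cc < canvas:
            out[rr, cc] = True
    return out


def rotate_image(img: np.ndarray, angle: float) -> np.ndarray:
    """Rotate a binary image about its center (CCW, y up), order-0."""
    img = np.asarray(img)
    if img.dtype != bool:
        img = img > 0
    if angle % 360.0 == 0.0:
        return img.copy()
    return ndi.rotate(img.astype(np.uint8), angle, reshape=False, order=0).astype(bool)


# ---------------------------------------------------------------------------
# candidate scoring
# ---------------------------------------------------------------------------

def _points_xy(img: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(img)
    return np.stack([cols.astype(float), -rows.astype(float)], axis=1)  # (x, y-up)


def _normalized_profile(pts: np.ndarray, ref: ReferenceShape) -> RadialProfile:
    """Profile of the point cloud after matching its bounding box to the
    reference box (anisotropic rescale, pixel-extent convention)."""
    x = pts[:, 0]
    y = pts[:, 1]
    lx = x.max() - x.min() + 1.0
    ly = y.max() - y.min() + 1.0
    ref_l, ref_w = ref.bbox
    return profile_from_points(x * (ref_l / lx), y * (ref_w / ly))


def score_rotation(
    pts: np.ndarray, angle: float, refs: tuple[ReferenceShape, ...]
) -> dict[str, float]:
    """Per-reference matching RMSD of the foreground points rotated by
    ``angle`` (degrees CCW) with per-reference bounding-box match."""
    a = np.radians(angle)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    rp = pts @ rot.T
    out = {}
    for ref in refs:
        out[ref.name] = rmsd(_normalized_profile(rp, ref), ref.profile)
    return out


def _best(scores: dict[str, float]) -> float:
    return min(scores.values())


# ---------------------------------------------------------------------------
# the three alignment methods
# ---------------------------------------------------------------------------

def align_eem(img: np.ndarray) -> AlignmentResult:
    """Equivalent-ellipse alignment: rotate until the major-axis angle is 0.

    Rotates by minus the signed ellipse angle only; no 180-degree
    disambiguation is attempted (the method's documented weakness).
    Circularly symmetric AOIs are flagged degenerate and left unrotated.
    """
    props = region_props(img)
    degenerate = props.minor / props.major > 0.98 or props.theta_ellipse == 0.0
    angle = 0.0 if degenerate else -props.theta_ellipse
    aligned = rotate_image(img, angle)
    return AlignmentResult(
        aligned=aligned, angle=angle % 360.0, method="eem",
        candidates=[(angle % 360.0, {})], degenerate=degenerate,
    )


def _extrema_candidates(props) -> list[float]:
    """Candidate rotations from the four lines joining consecutive
    extreme points clockwise around the object (top-right -> right-top,
    right-bottom -> bottom-right, bottom-left -> left-bottom,
    left-top -> top-left); a degenerate line (coincident points, e.g. an
    axis-aligned box corner) contributes the null rotation."""
    e = props.extrema
    pairs = [(e[1], e[2]), (e[3], e[4]), (e[5], e[6]), (e[7], e[0])]
    cands: list[float] = []
    for (x1, y1), (x2, y2) in pairs:
        if (x1, y1) == (x2, y2):
            beta = 0.0
        else:
            beta = np.degrees(np.arctan2(-(y2 - y1), x2 - x1))  # y up
            beta = (beta + 90.0) % 180.0 - 90.0  # line angle in (-90, 90]
        cand = float(np.rint(-beta)) % 360.0
        if cand not in cands:
            cands.append(cand)
    return cands[:4]


def align_extrema(
    img: np.ndarray, refs: tuple[ReferenceShape, ...] | None = None
) -> AlignmentResult:
    """Extrema alignment: make one extreme-point line horizontal.

    Up to four candidate rotations are scored by the minimum
    per-reference matching RMSD; the best-scoring candidate is applied.
    Candidate angles are rounded to whole degrees, making them a subset
    of the manual search grid.
    """
    refs = refs if refs is not None else reference_set()
    props = region_props(img)
    if len(set(props.extrema)) < 2:
        return AlignmentResult(
            aligned=img.copy(), angle=0.0, method="extrema",
            candidates=[(0.0, {})], degenerate=True,
        )
    pts = _points_xy(img)
    candidates = []
    for cand in _extrema_candidates(props):
        candidates.append((cand, score_rotation(pts, cand, refs)))
    best_angle, best_scores = min(candidates, key=lambda c: (_best(c[1]), c[0]))
    return AlignmentResult(
        aligned=rotate_image(img, best_angle), angle=best_angle, method="extrema",
        candidates=candidates, objective=_best(best_scores),
    )


def align_manual(
    img: np.ndarray, refs: tuple[ReferenceShape, ...] | None = None
) -> AlignmentResult:
    """Exhaustive alignment: scan rotations 0..359 degrees at 1-degree
    steps and keep the angle with the lowest min-over-references RMSD
    (smallest angle on ties)."""
    refs = refs if refs is not None else reference_set()
    pts = _points_xy(img)
    candidates = []
    for ang in range(N_THETA):
        candidates.append((float(ang), score_rotation(pts, float(ang), refs)))
    best_angle, best_scores = min(candidates, key=lambda c: (_best(c[1]), c[0]))
    return AlignmentResult(
        aligned=rotate_image(img, best_angle), angle=best_angle, method="manual",
        candidates=candidates, objective=_best(best_scores),
    )


def align(
    img: np.ndarray, method: str, refs: tuple[ReferenceShape, ...] | None = None
) -> AlignmentResult:
    """Dispatch to one of ``none``, ``eem``, ``extrema``, ``manual``."""
    if method == "none":
        return AlignmentResult(aligned=np.asarray(img) > 0, angle=0.0, method="none")
    if method == "eem":
        return align_eem(img)
    if method == "extrema":
        return align_extrema(img, refs)
    if method == "manual":
        return align_manual(img, refs)
    raise ValueError(f"unknown alignment method {method!r}")
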