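"""Synthetic deformation engine and labeled-corpus generator.

The engine reproduces the four elementary deformations used to build the
labeled test corpus of deformed reference shapes:

* **swelling / shrinkage** -- isotropic scaling by a factor ``S`` about the
  image center;
* **horizontal / vertical elongation (contraction)** -- scaling of one
  coordinate only;
* **convexity / concavity** -- a radial warp of the boundary about the AOI
  centroid driven by the cubic law ``rho + rho**3 * S / max(d)**2``.
  The convex warp applies the law as an inverse mapping (the resampling
  convention of MATLAB's ``imwarp``), which blunts high-radius directions
  and makes the shape rounder and more circle-like; the concave warp
  applies it as a forward mapping, which accentuates high-radius
  directions so that the sides between them appear caved-in.  Both warps
  are renormalized to the original bounding box so that they change
  *shape* (the l descriptor) while leaving the box dimensions (j, k)
  untouched and the area (i) nearly so, matching the ``0, 0, 0, +/-, 1``
  pattern taxonomy.

Each deformation pattern is encoded by the 5-tuple ``(i, j, k, l, m)``
over ``{+, 0, -}`` for the first four entries and ``{0, 1}`` for the
uniformity flag; the 12 codes and their corpus row counts follow the
benchmark design of the accompanying evaluation module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw

from .geometry import SHAPE_NAMES, ReferenceShape, reference_set

__all__ = [
    "PATTERN_CODES",
    "DEFAULT_PATTERN_COUNTS",
    "DeformationLabel",
    "apply_swelling",
    "apply_elongation",
    "apply_warp",
    "radial_warp_law",
    "compose_and_orient",
    "default_config",
    "generate_corpus",
]

#: The 12 deformation-pattern codes of the benchmark corpus.
PATTERN_CODES = (
    "0,0,0,0,0",    # undeformed
    "+,+,+,0,0",    # swelling / shrinkage
    "+,+,0,0,1",    # horizontal elongation / contraction
    "+,0,+,0,1",    # vertical elongation / contraction
    "0,0,0,-,1",    # concavity
    "+,+,+,-,1",    # swelling + concavity
    "+,+,0,-,1",    # horizontal elongation + concavity
    "+,0,+,-,1",    # vertical elongation + concavity
    "0,0,0,+,1",    # convexity
    "+,+,+,+,1",    # swelling + convexity
    "+,+,0,+,1",    # horizontal elongation + convexity
    "+,0,+,+,1",    # vertical elongation + convexity
)

#: Corpus row counts per pattern (total 4200): 120 undeformed, 240 per
#: single deformation, 480 per combined deformation.
DEFAULT_PATTERN_COUNTS = {
    "0,0,0,0,0": 120,
    "+,+,+,0,0": 240,
    "+,+,0,0,1": 240,
    "+,0,+,0,1": 240,
    "0,0,0,-,1": 240,
    "+,+,+,-,1": 480,
    "+,+,0,-,1": 480,
    "+,0,+,-,1": 480,
    "0,0,0,+,1": 240,
    "+,+,+,+,1": 480,
    "+,+,0,+,1": 480,
    "+,0,+,+,1": 480,
}


@dataclass(frozen=True)
class DeformationLabel:
    """Ground-truth description of one synthetic image.

    Scaling factors are 1.0 (or 0.0 for ``s_warp``) when the corresponding
    deformation is inactive; ``warp_sign`` is ``"none"``, ``"convex"`` or
    ``"concave"``; ``orientation`` is the final rotation in degrees.
    """

    pattern: str
    s_swell: float = 1.0
    s_hx: float = 1.0
    s_vx: float = 1.0
    s_warp: float = 0.0
    warp_sign: str = "none"
    orientation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in PATTERN_CODES:
            raise ValueError(f"unknown pattern code {self.pattern!r}")
        if min(self.s_swell, self.s_hx, self.s_vx) <= 0:
            raise ValueError("scaling factors must be positive")
        if not 0.0 <= self.orientation < 360.0:
            raise ValueError("orientation must lie in [0, 360)")
        if self.warp_sign not in ("none", "convex", "concave"):
            raise ValueError(f"bad warp sign {self.warp_sign!r}")


# ---------------------------------------------------------------------------
# affine deformations
# ---------------------------------------------------------------------------

def _affine_scale(img: np.ndarray, sx: float, sy: float) -> np.ndarray:
    """Scale about the image center, nearest-neighbor, re-binarized."""
    img = np.asarray(img)
    if img.dtype != bool:
        img = img > 0
    if sx == 1.0 and sy == 1.0:
        return img.copy()
    h, w = img.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    matrix = np.diag([1.0 / sy, 1.0 / sx])  # (row, col) inverse map
    offset = c - matrix @ c
    out = ndi.affine_transform(
        img.astype(np.uint8), matrix, offset=offset, order=0, mode="constant", cval=0
    ).astype(bool)
    if not out.any():
        raise ValueError("scaled AOI vanished")
    rows, cols = np.nonzero(out)
    if rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1:
        raise ValueError("scaled AOI exceeds the canvas")
    return out


def apply_swelling(img: np.ndarray, s: float) -> np.ndarray:
    """Isotropic scaling (swelling for S > 1, shrinkage for S < 1)."""
    if s <= 0:
        raise ValueError("scaling factor must be positive")
    return _affine_scale(img, s, s)


def apply_elongation(img: np.ndarray, axis: str, s: float) -> np.ndarray:
    """One-axis scaling: ``axis`` is ``"horizontal"`` or ``"vertical"``."""
    if s <= 0:
        raise ValueError("scaling factor must be positive")
    if axis == "horizontal":
        return _affine_scale(img, s, 1.0)
    if axis == "vertical":
        return _affine_scale(img, 1.0, s)
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


# ---------------------------------------------------------------------------
# radial warps
# ---------------------------------------------------------------------------

def radial_warp_law(d: np.ndarray | float, s: float, d_max: float) -> np.ndarray | float:
    """The cubic radial law ``d + d**3 * S / d_max**2``.

    At the direction attaining ``d = d_max`` the radial displacement is
    exactly ``S * d_max``.
    """
    d = np.asarray(d, dtype=float)
    return d + d**3 * (s / d_max**2)


def _fine_profile(img: np.ndarray, n_theta: int = 720, step: float = 0.25):
    """Outermost-crossing radial profile by dense ray marching.

    Returns (centroid_rowcol, theta_radians, distances)."""
    rows, cols = np.nonzero(img)
    cy, cx = rows.mean(), cols.mean()
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    r_max = float(np.hypot(*img.shape))
    t = np.arange(0.0, r_max / 2.0, step)
    # sample grid: (n_theta, n_steps)
    xs = cx + np.cos(theta)[:, None] * t[None, :]
    ys = cy - np.sin(theta)[:, None] * t[None, :]
    ri = np.clip(np.rint(ys).astype(int), 0, img.shape[0] - 1)
    ci = np.clip(np.rint(xs).astype(int), 0, img.shape[1] - 1)
    fg = img[ri, ci]
    # outermost foreground sample along each ray
    idx = fg.shape[1] - 1 - np.argmax(fg[:, ::-1], axis=1)
    d = np.where(fg.any(axis=1), t[idx], 0.0)
    return (cy, cx), theta, d


def _solve_inverse_law(d: np.ndarray, s: float, d_max: float) -> np.ndarray:
    """Solve ``rho + rho**3 S / d_max**2 = d`` for rho (Newton, monotone)."""
    rho = d / (1.0 + s * (d / d_max) ** 2)  # good starting guess
    k = s / d_max**2
    for _ in range(40):
        f = rho + k * rho**3 - d
        fp = 1.0 + 3.0 * k * rho**2
        step = f / fp
        rho = rho - step
        if np.max(np.abs(step)) < 1e-10:
            break
    return rho


def apply_warp(img: np.ndarray, s: float, sign: str, preserve: str = "bbox") -> np.ndarray:
    """Convex or concave radial warp of the AOI boundary.

    The boundary distance profile ``d(theta)`` about the centroid is
    remapped by the cubic radial law (inverse mapping for ``"convex"``,
    forward for ``"concave"``) and the interior re-filled as a polygon.

    ``preserve`` controls the renormalization that isolates the change of
    *shape* from the change of size:

    * ``"bbox"`` (default) -- rescale anisotropically so the bounding box
      equals the input box; the box dimensions (descriptors j, k) are
      unchanged and the residual area change stays small;
    * ``"area"`` -- rescale isotropically back to the input pixel area;
    * ``"none"`` -- raw remap.
    """
    if sign not in ("convex", "concave"):
        raise ValueError(f"sign must be 'convex' or 'concave', got {sign!r}")
    if preserve not in ("bbox", "area", "none"):
        raise ValueError(f"bad preserve mode {preserve!r}")
    if s < 0:
        raise ValueError("warp scaling factor must be non-negative")
    img = np.asarray(img)
    if img.dtype != bool:
        img = img > 0
    if not img.any():
        raise ValueError("empty image")
    if s == 0.0:
        return img.copy()

    (cy, cx), theta, d = _fine_profile(img)
    if (d <= 0).any():
        raise ValueError("centroid lies outside the AOI; warp undefined")
    d_max = float(d.max())
    if sign == "convex":
        d_new = _solve_inverse_law(d, s, d_max)
    else:
        d_new = np.asarray(radial_warp_law(d, s, d_max), dtype=float)
    if (d_new <= 0).any():
        raise ValueError("warp collapsed the boundary (d <= 0)")

    if preserve == "area":
        # match the continuous boundary areas so the pixel areas agree
        d_new = d_new * np.sqrt(_radial_area(d) / _radial_area(d_new))
    rr = cy - d_new * np.sin(theta)
    cc = cx + d_new * np.cos(theta)
    if preserve == "bbox":
        rows, cols = np.nonzero(img)
        rr = _map_span(rr, rows.min() - 0.5, rows.max() + 0.5)
        cc = _map_span(cc, cols.min() - 0.5, cols.max() + 0.5)
    out = _fill_polygon(img.shape, cy, cx, rr, cc)
    if not out.any():
        raise ValueError("warp collapsed the AOI")
    return out


def _radial_area(d: np.ndarray) -> float:
    """Area enclosed by a radial polygon with uniform angular spacing."""
    dtheta = 2.0 * np.pi / d.size
    return float(0.5 * np.sin(dtheta) * np.sum(d * np.roll(d, -1)))


def _map_span(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + (v - v.min()) * (hi - lo) / (v.max() - v.min())


def _fill_polygon(shape, cy, cx, rr, cc) -> np.ndarray:
    # expand by half a pixel about the centroid: ray-marched distances refer
    # to pixel centers, so the continuous boundary runs through the outer
    # pixel's center and the refill would otherwise lose a half-pixel ring
    r = np.hypot(rr - cy, cc - cx)
    f = (r + 0.5) / np.maximum(r, 1e-9)
    r_idx, c_idx = draw.polygon(cy + (rr - cy) * f, cx + (cc - cx) * f, shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[r_idx, c_idx] = True
    return out


# ---------------------------------------------------------------------------
# composition and corpus generation
# ---------------------------------------------------------------------------

def rotate_binary(img: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the image center (counterclockwise, y up), order-0."""
    img = np.asarray(img)
    if img.dtype != bool:
        img = img > 0
    if angle % 360.0 == 0.0:
        return img.copy()
    return ndi.rotate(img.astype(np.uint8), angle, reshape=False, order=0).astype(bool)


def compose_and_orient(shape: ReferenceShape, label: DeformationLabel) -> np.ndarray:
    """Build the deformed, rotated image a label describes.

    Operations are composed in the fixed order swelling -> horizontal
    elongation -> vertical elongation -> warp -> rotation.
    """
    img = shape.image
    img = apply_swelling(img, label.s_swell)
    img = apply_elongation(img, "horizontal", label.s_hx)
    img = apply_elongation(img, "vertical", label.s_vx)
    if label.warp_sign != "none":
        img = apply_warp(img, label.s_warp, label.warp_sign)
    return rotate_binary(img, label.orientation)


def default_config(scale: float = 1.0) -> dict:
    """Corpus configuration; ``scale`` shrinks every row count
    proportionally (rounded to a multiple of the 5 shapes)."""
    counts = {}
    for code, n in DEFAULT_PATTERN_COUNTS.items():
        m = max(5, int(round(n * scale / 5.0)) * 5)
        counts[code] = m
    return {
        "counts": counts,
        # sampled magnitudes: visibly deformed but non-degenerate
        "s_affine_range": [0.6, 0.9, 1.1, 1.4],   # union of [0.6,0.9] and [1.1,1.4]
        "s_convex_range": [0.05, 0.35],
        "s_concave_range": [0.05, 0.35],
        "side": 97,
        "canvas": 512,
    }


def _sample_affine(rng: np.random.Generator, lo1, hi1, lo2, hi2) -> float:
    if rng.random() < 0.5:
        return float(rng.uniform(lo1, hi1))
    return float(rng.uniform(lo2, hi2))


def sample_label(pattern: str, rng: np.random.Generator, config: dict) -> DeformationLabel:
    """Draw the scaling factors and orientation for one corpus image."""
    a1, a2, a3, a4 = config["s_affine_range"]
    cx1, cx2 = config["s_convex_range"]
    cc1, cc2 = config["s_concave_range"]
    i_code, j_code, k_code, l_code, _ = pattern.split(",")
    swelling = j_code != "0" and k_code != "0"
    s_swell = _sample_affine(rng, a1, a2, a3, a4) if swelling else 1.0
    s_hx = s_vx = 1.0
    if j_code != "0" and k_code == "0":
        s_hx = _sample_affine(rng, a1, a2, a3, a4)
    if k_code != "0" and j_code == "0":
        s_vx = _sample_affine(rng, a1, a2, a3, a4)
    if l_code == "+":
        warp_sign, s_warp = "convex", float(rng.uniform(cx1, cx2))
    elif l_code == "-":
        warp_sign, s_warp = "concave", float(rng.uniform(cc1, cc2))
    else:
        warp_sign, s_warp = "none", 0.0
    orientation = float(rng.uniform(0.0, 360.0))
    seed = int(rng.integers(0, 2**31 - 1))
    return DeformationLabel(
        pattern=pattern, s_swell=s_swell, s_hx=s_hx, s_vx=s_vx,
        s_warp=s_warp, warp_sign=warp_sign, orientation=orientation, seed=seed,
    )


MANIFEST_COLUMNS = [
    "path", "shape", "pattern", "s_swell", "s_hx", "s_vx",
    "s_warp", "warp_sign", "orientation", "seed",
]


def generate_corpus(config: dict, master_seed: int, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Generate a labeled corpus of deformed reference-shape images.

    Every pattern row is split equally across the five reference shapes.
    With ``out_dir`` the images are written as PNG files and the manifest
    as ``manifest.csv``; otherwise images are kept in memory in an
    ``image`` column.  Deterministic for a fixed ``(config, master_seed)``.
    """
    rng = np.random.default_rng(master_seed)
    refs = {r.name: r for r in reference_set(config.get("side", 97), config.get("canvas", 512))}
    records = []
    images = []
    for pattern in PATTERN_CODES:
        n = int(config["counts"].get(pattern, 0))
        if n == 0:
            continue
        if n % len(SHAPE_NAMES):
            raise ValueError(f"count {n} for {pattern!r} not divisible by {len(SHAPE_NAMES)} shapes")
        per_shape = n // len(SHAPE_NAMES)
        for shape_name in SHAPE_NAMES:
            for idx in range(per_shape):
                label = sample_label(pattern, rng, config)
                img = compose_and_orient(refs[shape_name], label)
                fname = f"{pattern.replace(',', '').replace('+', 'p').replace('-', 'm')}_{shape_name}_{idx:04d}.png"
                rec = {"path": fname, "shape": shape_name, **asdict(label)}
                records.append(rec)
                images.append(img)
    manifest = pd.DataFrame.from_records(records, columns=MANIFEST_COLUMNS)
    if out_dir is None:
        manifest["image"] = images
        return manifest
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .io import save_image  # lazy: keeps deform importable without IO deps
    for rec, img in zip(records, images):
        save_image(out / rec["path"], img)
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "config.json").write_text(json.dumps(config, indent=2))
    return manifest
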