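"""Batch benchmarking and time-series descriptor reports.

``run_benchmark`` reproduces the accuracy-table protocol: every corpus
image is identified with each requested alignment method and the percent
of correct identifications is tabulated per deformation pattern, with
both a row-averaged and an image-weighted overall figure.  External
classifier predictions (e.g. from a CNN) can be merged from a CSV as
additional columns.

``analyze_series`` follows one specimen through a drying (or other)
image sequence: frame 0 defines the undeformed baseline state, and every
frame is reported with its identified shape, i/j/k/l/alpha_u/m
descriptors relative to frame 0, and the baseline shape parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import segment
from .baselines import BaselineReport, baseline_report
from .deform import PATTERN_CODES
from .geometry import ReferenceShape, reference_set, region_props
from .identify import (
    Descriptors,
    ShapeMatch,
    compute_descriptors,
    match_shape,
    reference_state,
)
from .io import load_image

__all__ = ["AccuracyTable", "SeriesRecord", "SeriesReport", "run_benchmark", "analyze_series"]

logger = logging.getLogger("softshape")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AccuracyTable:
    """Per-pattern, per-method percent accuracies.

    ``rows`` is indexed by pattern code with one accuracy column per
    method (plus any merged external prediction columns) and an
    ``n_images`` column; ``overall_row_mean`` is the unweighted mean over
    pattern rows, ``overall_image_mean`` the image-weighted mean.
    """

    rows: pd.DataFrame
    overall_row_mean: dict[str, float]
    overall_image_mean: dict[str, float]


def _iter_images(manifest: pd.DataFrame):
    root = Path(manifest.attrs.get("root", "."))
    for idx, rec in manifest.iterrows():
        if "image" in manifest.columns and rec.get("image") is not None:
            yield idx, rec, np.asarray(rec["image"]) > 0
            continue
        path = root / rec["path"]
        if not path.exists():
            logger.warning("missing image %s: skipped", path)
            yield idx, rec, None
            continue
        yield idx, rec, load_image(path) > 127


def run_benchmark(
    manifest: pd.DataFrame,
    methods: tuple[str, ...] = ("none", "eem", "extrema", "manual"),
    refs: tuple[ReferenceShape, ...] | None = None,
    external_predictions: pd.DataFrame | None = None,
) -> AccuracyTable:
    """Identify every manifest image under each alignment method and
    tabulate percent accuracy per deformation pattern.

    The manifest needs ``shape`` and ``pattern`` columns and either an
    in-memory ``image`` column or a ``path`` column (with the manifest's
    origin directory in ``manifest.attrs['root']``).  An optional
    ``external_predictions`` frame (columns: ``path`` plus one column per
    classifier) is merged as extra accuracy columns.  Deterministic for
    a fixed manifest.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    refs = refs if refs is not None else reference_set()
    pred_cols: dict[str, pd.Series] = {}
    if external_predictions is not None:
        merged = manifest.merge(external_predictions, on="path", how="left", suffixes=("", "_ext"))
        for col in external_predictions.columns:
            if col != "path":
                pred_cols[col] = merged[col]

    correct: dict[str, list[bool]] = {m: [] for m in methods}
    for name in pred_cols:
        correct[name] = []
    patterns: list[str] = []
    for idx, rec, img in _iter_images(manifest):
        if img is None:
            continue
        patterns.append(rec["pattern"])
        for m in methods:
            match = match_shape(img, refs, method=m)
            ok = match.label == rec["shape"]
            correct[m].append(ok)
            logger.debug(
                "%s method=%s angle=%.1f label=%s truth=%s rmsd=%s",
                rec.get("path", idx), m, match.alignment.angle, match.label,
                rec["shape"], {k: round(v, 2) for k, v in match.rmsd_by_shape.items()},
            )
        for name, series in pred_cols.items():
            correct[name].append(series.loc[idx] == rec["shape"])

    df = pd.DataFrame({"pattern": patterns, **{m: v for m, v in correct.items()}})
    order = [p for p in PATTERN_CODES if p in set(patterns)]
    grouped = df.groupby("pattern", sort=False)
    rows = pd.DataFrame({
        "n_images": grouped.size(),
        **{m: grouped[m].mean() * 100.0 for m in correct},
    }).reindex(order)
    overall_row = {m: float(rows[m].mean()) for m in correct}
    overall_img = {m: float(df[m].mean() * 100.0) for m in correct}
    return AccuracyTable(rows=rows, overall_row_mean=overall_row, overall_image_mean=overall_img)


# ---------------------------------------------------------------------------
# series analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesRecord:
    """One frame of a specimen series."""

    frame: int
    covariate: float | None
    match: ShapeMatch | None
    descriptors: Descriptors | None
    baselines: BaselineReport | None
    error: str | None = None


@dataclass(frozen=True)
class SeriesReport:
    """Per-frame records plus the log of shape-label transitions."""

    records: list[SeriesRecord]
    transitions: list[tuple[int, str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"frame": r.frame, "covariate": r.covariate, "error": r.error}
            if r.match is not None:
                row["shape"] = r.match.label
            if r.descriptors is not None:
                d = r.descriptors
                row.update(i=d.i, j=d.j, k=d.k, l=d.l, alpha_u=d.alpha_u, m=d.m)
            if r.baselines is not None:
                row.update(
                    extent=r.baselines.extent, fractal_dim=r.baselines.fractal_dim,
                    shape_ig=r.baselines.shape_ig,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def analyze_series(
    frames: list,
    covariates: list[float] | None = None,
    method: str = "extrema",
    refs: tuple[ReferenceShape, ...] | None = None,
) -> SeriesReport:
    """Descriptor report for an ordered image series.

    ``frames`` may be file paths or arrays (grayscale or binary).  Frame
    0 defines the baseline state; its descriptors are exactly
    (100, 100, 100, 100, uniform).  A frame that cannot be segmented is
    flagged and the series continues.
    """
    if len(frames) == 0:
        raise ValueError("empty series")
    refs = refs if refs is not None else reference_set()
    covs = covariates if covariates is not None else [None] * len(frames)
    records: list[SeriesRecord] = []
    transitions: list[tuple[int, str, str]] = []
    ref_state = None
    prev_label = None
    for n, frame in enumerate(frames):
        try:
            raw = load_image(frame) if isinstance(frame, (str, Path)) else np.asarray(frame)
            binary = segment(raw)
            props = region_props(binary)
            if ref_state is None:
                ref_state = reference_state(props)
            match = match_shape(binary, refs, method=method)
            desc = compute_descriptors(binary, ref_state)
            base = baseline_report(binary, props)
        except (ValueError, OSError, RuntimeError) as exc:  # unreadable or unsegmentable frame
            logger.warning("frame %d failed: %s", n, exc)
            records.append(SeriesRecord(frame=n, covariate=covs[n], match=None,
                                        descriptors=None, baselines=None, error=str(exc)))
            continue
        records.append(SeriesRecord(frame=n, covariate=covs[n], match=match,
                                    descriptors=desc, baselines=base))
        if prev_label is not None and match.label != prev_label:
            transitions.append((n, prev_label, match.label))
        prev_label = match.label
    return SeriesReport(records=records, transitions=transitions)
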