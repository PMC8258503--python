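"""Basement-membrane irregularity via the coefficient of variation of a
linearized intensity trace.

A capillary wall is traced manually as a polyline over the micrograph; the
intensity along it is resampled to a fixed-length 1-D profile (default
180 samples, matching the 1x180-px trace the workflow standardizes on) and
summarized by the coefficient of variation CV = sd/mean. Smooth, evenly
stained membranes give low CV; granular or dimpled ones give high CV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .images import GrayImage

__all__ = [
    "PolylineROI",
    "TraceProfile",
    "TraceStats",
    "read_polyline",
    "extract_trace",
    "trace_cv",
    "cv_batch",
]

logger = logging.getLogger(__name__)

DEFAULT_TRACE_LENGTH = 180


@dataclasses.dataclass(frozen=True)
class PolylineROI:
    """Ordered subpixel vertices (x, y) of a manual membrane trace."""

    vertices: np.ndarray
    target_length: int = DEFAULT_TRACE_LENGTH

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("PolylineROI requires >= 2 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("polyline vertices must be finite")
        seg = np.diff(v, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("consecutive polyline vertices must not coincide")
        if self.target_length < 2:
            raise ValueError("target_length must be >= 2")
        object.__setattr__(self, "vertices", v)

    def arc_length(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def reversed(self) -> "PolylineROI":
        return PolylineROI(self.vertices[::-1].copy(), self.target_length)


@dataclasses.dataclass(frozen=True)
class TraceProfile:
    """Fixed-length linearized intensity signal sampled along a polyline."""

    values: np.ndarray
    source_roi: PolylineROI | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 2:
            raise ValueError("trace profile requires >= 2 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")
        if self.source_roi is not None and v.size != self.source_roi.target_length:
            raise ValueError(
                f"profile length {v.size} != roi target_length "
                f"{self.source_roi.target_length}"
            )
        object.__setattr__(self, "values", v)


@dataclasses.dataclass(frozen=True)
class TraceStats:
    """Mean, standard deviation and coefficient of variation of a trace."""

    mean: float
    sd: float
    cv: float
    ddof: int = 0


def read_polyline(path: str | Path, target_length: int = DEFAULT_TRACE_LENGTH) -> PolylineROI:
    """Load a polyline from CSV (columns ``x,y``, header required) or a
    JSON list of ``[x, y]`` pairs. Coordinates are 0-based, x = column."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        pairs = json.loads(path.read_text())
        return PolylineROI(np.asarray(pairs, dtype=float), target_length)
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise ValueError(f"{path}: polyline CSV requires columns 'x' and 'y'")
    return PolylineROI(df[["x", "y"]].to_numpy(dtype=float), target_length)


def _sample_positions(roi: PolylineROI) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) coordinates of target_length points equally spaced in arc length."""
    v = roi.vertices
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    t = np.linspace(0.0, total, roi.target_length)
    idx = np.clip(np.searchsorted(cum, t, side="right") - 1, 0, len(seg_len) - 1)
    frac = (t - cum[idx]) / seg_len[idx]
    pts = v[idx] + frac[:, None] * seg[idx]
    return pts[:, 0], pts[:, 1]


def extract_trace(
    img: GrayImage,
    roi: PolylineROI,
    interpolation: Literal["bilinear", "nearest"] = "bilinear",
) -> TraceProfile:
    """Resample the image along the polyline into a fixed-length profile.

    The polyline is re-parameterized by arc length and sampled at
    ``target_length`` equally spaced positions; intensities are read by
    bilinear interpolation (``nearest`` available by configuration). A
    vertex outside the image is rejected with its index. Traces whose arc
    length falls short of ``target_length`` pixels are upsampled, with a
    warning.
    """
    v = roi.vertices
    for k, (x, y) in enumerate(v):
        if not (0.0 <= x <= img.width - 1 and 0.0 <= y <= img.height - 1):
            raise ValueError(
                f"polyline vertex {k} at ({x}, {y}) lies outside the "
                f"{img.width}x{img.height} image"
            )
    if roi.arc_length() < roi.target_length - 1:
        logger.warning(
            "trace arc length %.1f px < target %d samples; profile is upsampled",
            roi.arc_length(), roi.target_length,
        )
    xs, ys = _sample_positions(roi)
    order = {"bilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    values = map_coordinates(img.pixels, [ys, xs], order=order, mode="nearest")
    return TraceProfile(values=values, source_roi=roi)


def trace_cv(profile: TraceProfile, ddof: int = 0) -> TraceStats:
    """Coefficient of variation of a linearized trace.

    Uses the population standard deviation (divisor n) by default: the
    trace is the entire measured object, not a sample from it. ``ddof=1``
    switches to the sample convention.
    """
    values = profile.values
    mean = float(values.mean())
    if mean <= 0:
        raise ValueError(f"trace mean {mean} <= 0: CV undefined")
    # exactly constant traces have sd 0 by definition; summation roundoff
    # must not turn that into a spurious ~1e-16 CV
    sd = 0.0 if np.ptp(values) == 0 else float(values.std(ddof=ddof))
    return TraceStats(mean=mean, sd=sd, cv=sd / mean, ddof=ddof)


def cv_batch(
    profiles: Sequence[TraceProfile],
    subjects: Sequence[str] | None = None,
    trace_ids: Sequence[str] | None = None,
    ddof: int = 0,
) -> pd.DataFrame:
    """CV per trace plus per-subject mean rows (tidy frame, ``kind`` column)."""
    if len(profiles) == 0:
        raise ValueError("cv_batch requires at least one trace")
    if subjects is None:
        subjects = ["subject"] * len(profiles)
    if trace_ids is None:
        trace_ids = [f"trace{i:03d}" for i in range(len(profiles))]
    if not (len(subjects) == len(trace_ids) == len(profiles)):
        raise ValueError("profiles, subjects and trace_ids must have equal length")

    rows = []
    for prof, subj, tid in zip(profiles, subjects, trace_ids):
        s = trace_cv(prof, ddof=ddof)
        rows.append(
            {
                "kind": "roi",
                "roi_id": tid,
                "subject": subj,
                "mean": s.mean,
                "sd": s.sd,
                "cv": s.cv,
            }
        )
    df = pd.DataFrame(rows)
    for subj in dict.fromkeys(subjects):
        sub = df[(df["kind"] == "roi") & (df["subject"] == subj)]
        rows.append(
            {
                "kind": "subject_mean",
                "roi_id": "",
                "subject": subj,
                "mean": sub["mean"].mean(),
                "sd": sub["sd"].mean(),
                "cv": sub["cv"].mean(),
            }
        )
    return pd.DataFrame(rows)
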