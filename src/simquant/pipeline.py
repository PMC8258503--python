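"""Batch pipeline: ROI manifests, run configuration, and the per-metric
driver that turns a manifest of micrograph ROIs into a results table.

A manifest is a CSV with one row per ROI:

    subject,roi_id,image,kind,x,y,size,trace

``kind`` is ``square`` (payload: ``x``, ``y``, ``size`` — blank size means
use the configured default) or ``polyline`` (payload: ``trace``, a path to
a CSV/JSON polyline). Paths are resolved relative to the manifest file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal

import pandas as pd

from . import footprocess, membrane, mitochondria
from .fourier import BandSpec
from .images import extract_square_roi, read_image
from .membrane import extract_trace, read_polyline

__all__ = ["RunConfig", "read_manifest", "run_pipeline", "read_results"]

logger = logging.getLogger(__name__)

Metric = Literal["footprocess", "mito", "membrane"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults are the reference protocol values
    (128-px square ROIs, the (1/4, 1/16) spectral band, 180-sample traces,
    mean-fill circular windowing, population-SD CV)."""

    band_outer: float = 1 / 4
    band_inner: float = 1 / 16
    roi_size: int = 128
    fill: str = "mean"
    score_flavor: Literal["normalized", "raw"] = "normalized"
    sd_ddof: int = 0
    trace_length: int = 180
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        BandSpec(self.band_outer, self.band_inner)  # validates ordering
        if self.roi_size < 8 or self.roi_size % 2:
            raise ValueError("roi_size must be even and >= 8")
        if self.trace_length < 2:
            raise ValueError("trace_length must be >= 2")
        if self.sd_ddof not in (0, 1):
            raise ValueError("sd_ddof must be 0 (population) or 1 (sample)")

    @property
    def band(self) -> BandSpec:
        return BandSpec(self.band_outer, self.band_inner)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from JSON or simple ``key = value`` text."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = value.strip()
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in data.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cls, key, None)
            field_default = cls.__dataclass_fields__[key].default
            caster = type(field_default)
            kwargs[key] = caster(value) if not isinstance(value, caster) else value
        return cls(**kwargs)


_MANIFEST_COLUMNS = ["subject", "roi_id", "image", "kind"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a manifest CSV; resolves file paths and checks
    that referenced files exist and roi_ids are unique."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject": str, "roi_id": str})
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    if df["roi_id"].duplicated().any():
        dupes = df.loc[df["roi_id"].duplicated(), "roi_id"].tolist()
        raise ValueError(f"duplicate roi_ids in manifest: {dupes}")
    base = path.parent
    df["image"] = [str((base / p).resolve()) if not Path(p).is_absolute() else p for p in df["image"]]
    if "trace" in df.columns:
        df["trace"] = [
            str((base / p).resolve()) if isinstance(p, str) and not Path(p).is_absolute() else p
            for p in df["trace"]
        ]
    for _, row in df.iterrows():
        if not Path(row["image"]).exists():
            raise FileNotFoundError(f"manifest row {row['roi_id']}: image not found: {row['image']}")
        if row["kind"] == "polyline" and not Path(row["trace"]).exists():
            raise FileNotFoundError(f"manifest row {row['roi_id']}: trace not found: {row['trace']}")
    return df


def _config_header(config: RunConfig, metric: str) -> list[str]:
    items = dataclasses.asdict(config)
    parts = ", ".join(f"{k}={v}" for k, v in items.items())
    return [f"# simquant metric={metric}", f"# config: {parts}"]


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig,
    metric: Metric,
    out_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply one metric to every manifest row; per-subject means appended.

    Rows that fail (unreadable image, out-of-bounds ROI, ...) are logged,
    collected into the returned failure list, and do not stop the run.
    Returns ``(results, failures)``; when ``out_csv`` is given the results
    are also written with the configuration echoed as ``#`` header lines.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    logger.info(
        "run_pipeline metric=%s band=(%g, %g) roi_size=%d trace_length=%d fill=%s",
        metric, config.band_outer, config.band_inner, config.roi_size,
        config.trace_length, config.fill,
    )
    images, subjects, roi_ids = [], [], []
    profiles = []
    failures: list[dict] = []
    for _, row in manifest.iterrows():
        try:
            img = read_image(row["image"])
            if row["kind"] == "square":
                def _intval(key: str, default: int) -> int:
                    val = row.get(key)
                    return default if val is None or pd.isna(val) else int(val)

                x = _intval("x", 0)
                y = _intval("y", 0)
                size = _intval("size", config.roi_size)
                roi = (
                    img
                    if (x, y) == (0, 0) and img.pixels.shape == (size, size)
                    else extract_square_roi(img, (x, y), size)
                )
                images.append(roi)
            elif row["kind"] == "polyline":
                poly = read_polyline(row["trace"], target_length=config.trace_length)
                profiles.append(extract_trace(img, poly))
            else:
                raise ValueError(f"unknown roi kind {row['kind']!r}")
            subjects.append(row["subject"])
            roi_ids.append(row["roi_id"])
        except Exception as exc:  # per-row isolation is the contract
            logger.error("row %s failed: %s", row["roi_id"], exc)
            failures.append({"roi_id": row["roi_id"], "error": str(exc)})

    if metric == "footprocess":
        results = footprocess.score_roi_batch(images, config.band, subjects, roi_ids)
    elif metric == "mito":
        results = mitochondria.damage_batch(images, subjects, roi_ids, fill=config.fill)
    elif metric == "membrane":
        results = membrane.cv_batch(profiles, subjects, roi_ids, ddof=config.sd_ddof)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    if out_csv is not None:
        out_csv = Path(out_csv)
        with open(out_csv, "w") as fh:
            for line in _config_header(config, metric):
                fh.write(line + "\n")
            results.to_csv(fh, index=False)
    return results, failures


def read_results(path: str | Path) -> pd.DataFrame:
    """Re-parse a results CSV written by :func:`run_pipeline`."""
    return pd.read_csv(path, comment="#")
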