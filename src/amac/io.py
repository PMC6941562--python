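"""Raster and tabular I/O: section images, ROI masks, reports, configs.

Images go through imageio (PNG/TIFF/JPEG); everything is normalized to
8-bit RGB(A) on read and errors are raised, with the offending path in the
message, rather than silently converted.  Measurement tables round-trip as
CSV with ``NA`` markers for sections lacking an ROI (never silent zeros),
and reports can additionally be written as XLSX spreadsheets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .morphometry import (SectionMeasurement, SectionSeries, SeriesSummary,
                          round_pct)
from .segmentation import ThresholdScheme

__all__ = [
    "ImageFormatError",
    "read_section_image",
    "read_roi_mask",
    "ReportRow",
    "write_report",
    "read_measurements_csv",
    "write_measurements_csv",
    "load_scheme",
    "save_scheme",
]

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


class ImageFormatError(ValueError):
    """An image could not be read as 8-bit RGB(A)."""


def read_section_image(path: str | Path) -> np.ndarray:
    """Read a section image as an (H, W, 3|4) uint8 array.

    Grayscale input is expanded to RGB; alpha is preserved when present.

    Raises
    ------
    ImageFormatError
        For missing files, unsupported formats, or non-8-bit channel depth
        (16-bit TIFFs must be converted upstream — rescaling would move
        pixels across class thresholds silently).
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such image file: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ImageFormatError(
            f"unsupported image format {path.suffix!r} for {path}; "
            "expected PNG, TIFF or JPEG"
        )
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise ImageFormatError(
            f"{path}: expected 8-bit channels, got dtype {arr.dtype}"
        )
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ImageFormatError(
            f"{path}: expected RGB or RGBA image, got shape {arr.shape}"
        )
    return arr


def read_roi_mask(path: str | Path, expected_dims: tuple[int, int]) -> np.ndarray:
    """Read a binary ROI mask: any nonzero pixel (any channel) is true.

    Raises
    ------
    ImageFormatError
        If the mask's dimensions differ from ``expected_dims`` (both sizes
        are named in the message) or the file cannot be read.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such mask file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ImageFormatError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    if arr.shape != tuple(expected_dims):
        raise ImageFormatError(
            f"mask {path} has shape {arr.shape}, expected {tuple(expected_dims)}"
        )
    return arr > 0


@dataclass
class ReportRow:
    """One report line, mirroring the per-section measurement layout."""

    section_index: int
    total_area_px: int
    infarct_area_px: int
    infarct_pct: float
    collagen_pct: float | None = None
    fibrosis_pct: float | None = None


_REPORT_COLUMNS = ["section_index", "total_area_px", "infarct_area_px",
                   "infarct_pct", "collagen_pct", "fibrosis_pct"]


def _report_frame(rows: Sequence[ReportRow],
                  summary: SeriesSummary | None,
                  decimal: str = ".") -> pd.DataFrame:
    recs = []
    for r in rows:
        recs.append({
            "section_index": r.section_index,
            "total_area_px": r.total_area_px,
            "infarct_area_px": r.infarct_area_px,
            "infarct_pct": round_pct(r.infarct_pct),
            "collagen_pct": round_pct(r.collagen_pct),
            "fibrosis_pct": round_pct(r.fibrosis_pct),
        })
    df = pd.DataFrame(recs, columns=_REPORT_COLUMNS)
    if summary is not None:
        footer = pd.DataFrame([
            {"section_index": "Average of infarction area (%)",
             "infarct_pct": round_pct(summary.average_infarct_pct),
             "collagen_pct": round_pct(summary.avg_collagen_pct),
             "fibrosis_pct": round_pct(summary.avg_fibrosis_pct)},
            {"section_index": "Volume infarction (%)",
             "infarct_pct": round_pct(summary.volumetric_infarct_pct)},
        ], columns=_REPORT_COLUMNS)
        df = pd.concat([df, footer], ignore_index=True)
    if decimal != ".":
        for col in ("infarct_pct", "collagen_pct", "fibrosis_pct"):
            df[col] = df[col].map(
                lambda v: str(v).replace(".", decimal) if pd.notna(v) else v
            )
    return df


def write_report(rows: Sequence[ReportRow], summary: SeriesSummary | None,
                 path: str | Path, fmt: str = "csv",
                 decimal: str = ".") -> Path:
    """Write a per-section report with summary footer rows.

    The footer appends the average infarct percentage (with ROI averages
    where available) and the volumetric infarct percentage, matching the
    layout of a serial-section morphometry report.  ``fmt`` is ``"csv"``
    (always available) or ``"xlsx"``; ``decimal`` may be set to ``","``
    for locales printing decimal commas.

    Raises
    ------
    ValueError
        If ``rows`` is empty.
    """
    if not rows:
        raise ValueError("report needs at least one row")
    path = Path(path)
    df = _report_frame(rows, summary, decimal=decimal)
    if fmt == "csv":
        df.to_csv(path, index=False, na_rep="NA")
    elif fmt == "xlsx":
        df.to_excel(path, index=False, na_rep="NA", engine="openpyxl")
    else:
        raise ValueError(f"unknown report format {fmt!r}; use 'csv' or 'xlsx'")
    return path


_MEASUREMENT_COLUMNS = [
    "section_index", "total_area_px", "infarct_area_px",
    "scar_collagen_px", "scar_total_px", "remote_fibrosis_px",
    "remote_total_px",
]


def write_measurements_csv(series: SectionSeries, path: str | Path) -> Path:
    """Write raw per-section pixel counts; NA for missing ROI counts."""
    path = Path(path)
    recs = []
    for m in series.sections:
        recs.append({c: getattr(m, c) for c in _MEASUREMENT_COLUMNS})
    df = pd.DataFrame(recs, columns=_MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False, na_rep="NA")
    return path


def read_measurements_csv(path: str | Path, spacing_um: float = 300.0,
                          n_px_per_spacing: int = 1) -> SectionSeries:
    """Read a per-section pixel-count table into a :class:`SectionSeries`.

    Lets measurement tables from any segmentation source (including the
    bundled example data) enter the morphometry pipeline directly,
    bypassing image segmentation.  ``NA``/empty cells become missing ROI
    counts.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("section_index", "total_area_px", "infarct_area_px")
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    sections = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _MEASUREMENT_COLUMNS:
            v = row.get(col)
            kwargs[col] = None if v is None or pd.isna(v) else int(v)
        sections.append(SectionMeasurement(**kwargs))
    return SectionSeries(sections=sections, spacing_um=spacing_um,
                         n_px_per_spacing=n_px_per_spacing)


def load_scheme(path: str | Path) -> ThresholdScheme:
    """Load a threshold scheme from a YAML mapping of parameter names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ThresholdScheme.from_dict(data)


def save_scheme(scheme: ThresholdScheme, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(scheme.to_dict(), fh, sort_keys=False)
    return path
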