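"""End-to-end batch run: segment sections, measure, report, build the stack.

One :class:`RunConfig` drives the whole chain for a directory of section
images: per-pixel classification, optional scar/remote ROI restriction,
per-section measurements, a summary report (CSV, optionally XLSX), class
overlays with transparent background, and an optional voxel-stack export.
Per-section class counts are logged at INFO level so every number in the
report can be audited from the log.  A failing section is recorded and the
run continues; any failure makes the final status nonzero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as amio
from .morphometry import (SectionMeasurement, SectionSeries,
                          infarct_fraction_section, summarize_series)
from .segmentation import (ColorClass, PixelClassMap, ThresholdScheme,
                           count_roi_classes, render_overlay, segment_section)
from .stack import align_sections, build_stack, export_stack_slices

import imageio.v3 as iio

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("amac")


@dataclass
class RunConfig:
    """Configuration of a batch morphometry run.

    ``inputs`` lists section images apex-to-base; if a directory or glob
    resolved them, order is lexicographic on the (zero-padded) filenames.
    ``scar_rois`` / ``remote_rois`` map section position (0-based) to mask
    paths.  ``n_px_per_spacing`` is the voxel slabs per section used for
    the stack and volumetric weighting (cancels when uniform).
    """

    inputs: list[Path]
    output_dir: Path
    scheme: ThresholdScheme = field(default_factory=ThresholdScheme)
    spacing_um: float = 300.0
    n_px_per_spacing: int = 1
    scar_rois: dict[int, Path] = field(default_factory=dict)
    remote_rois: dict[int, Path] = field(default_factory=dict)
    write_overlays: bool = True
    write_xlsx: bool = False
    export_stack: bool = False
    decimal: str = "."

    def __post_init__(self) -> None:
        self.inputs = [Path(p) for p in self.inputs]
        self.output_dir = Path(self.output_dir)
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be > 0")
        if self.n_px_per_spacing < 1:
            raise ValueError("n_px_per_spacing must be >= 1")


@dataclass
class PipelineResult:
    exit_status: int
    series: SectionSeries | None
    summary: object | None
    report_path: Path | None
    failures: list[tuple[Path, str]]
    class_maps: list[PixelClassMap] = field(default_factory=list)


def collect_inputs(pattern_or_dir: str | Path) -> list[Path]:
    """Resolve a directory or glob to an ordered list of section images."""
    p = Path(pattern_or_dir)
    if p.is_dir():
        paths = [q for q in p.iterdir()
                 if q.suffix.lower() in amio._SUPPORTED_SUFFIXES]
    else:
        paths = [Path(q) for q in sorted(p.parent.glob(p.name))]
    paths = sorted(paths, key=lambda q: q.name)
    if not paths:
        raise FileNotFoundError(f"no section images match {pattern_or_dir}")
    return paths


def _measure_section(idx: int, image_path: Path, cfg: RunConfig
                     ) -> tuple[SectionMeasurement, PixelClassMap]:
    img = amio.read_section_image(image_path)
    cmap = segment_section(img, cfg.scheme)
    logger.info("section %d (%s): counts %s", idx, image_path.name,
                {c.name: n for c, n in cmap.counts.items()})
    kwargs: dict = {
        "section_index": idx,
        "infarct_area_px": cmap.counts[ColorClass.COLLAGEN],
        "total_area_px": cmap.tissue_px(),
    }
    pos = idx - 1
    if pos in cfg.scar_rois:
        roi = amio.read_roi_mask(cfg.scar_rois[pos], cmap.labels.shape)
        rc = count_roi_classes(cmap, roi)
        kwargs["scar_collagen_px"] = rc[ColorClass.COLLAGEN]
        kwargs["scar_total_px"] = (rc[ColorClass.COLLAGEN] + rc[ColorClass.MUSCLE]
                                   + rc[ColorClass.OTHER_TISSUE])
    if pos in cfg.remote_rois:
        roi = amio.read_roi_mask(cfg.remote_rois[pos], cmap.labels.shape)
        rc = count_roi_classes(cmap, roi)
        kwargs["remote_fibrosis_px"] = rc[ColorClass.COLLAGEN]
        kwargs["remote_total_px"] = (rc[ColorClass.COLLAGEN] + rc[ColorClass.MUSCLE]
                                     + rc[ColorClass.OTHER_TISSUE])
    return SectionMeasurement(**kwargs), cmap


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run segmentation → morphometry → report (→ stack) over all sections.

    Deterministic given the config and input bytes.  Returns exit status 0
    when every section succeeded, 1 otherwise; per-section failures are
    collected, not fatal.
    """
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    sections: list[SectionMeasurement] = []
    maps: list[PixelClassMap] = []
    failures: list[tuple[Path, str]] = []
    for i, path in enumerate(cfg.inputs, start=1):
        try:
            m, cmap = _measure_section(i, path, cfg)
        except Exception as exc:
            logger.error("section %d (%s) failed: %s", i, path, exc)
            failures.append((path, str(exc)))
            continue
        sections.append(m)
        maps.append(cmap)
        if cfg.write_overlays:
            overlay = render_overlay(
                cmap, [ColorClass.COLLAGEN, ColorClass.MUSCLE,
                       ColorClass.OTHER_TISSUE])
            iio.imwrite(cfg.output_dir / f"overlay_{i:03d}.png", overlay)

    if not sections:
        return PipelineResult(1, None, None, None, failures)

    series = SectionSeries(sections=sections, spacing_um=cfg.spacing_um,
                           n_px_per_spacing=cfg.n_px_per_spacing)
    summary = summarize_series(series)
    amio.write_measurements_csv(series, cfg.output_dir / "measurements.csv")
    rows = [
        amio.ReportRow(
            section_index=m.section_index,
            total_area_px=m.total_area_px,
            infarct_area_px=m.infarct_area_px,
            infarct_pct=infarct_fraction_section(m),
            collagen_pct=summary.per_section_collagen_pct[j],
            fibrosis_pct=summary.per_section_fibrosis_pct[j],
        )
        for j, m in enumerate(series.sections)
    ]
    report_path = amio.write_report(rows, summary,
                                    cfg.output_dir / "report.csv",
                                    decimal=cfg.decimal)
    if cfg.write_xlsx:
        amio.write_report(rows, summary, cfg.output_dir / "report.xlsx",
                          fmt="xlsx", decimal=cfg.decimal)
    if cfg.export_stack:
        aligned, offsets, _ = align_sections(maps)
        stack = build_stack(aligned, z_step_px=cfg.n_px_per_spacing,
                            section_indices=[m.section_index
                                             for m in series.sections],
                            offsets=offsets, spacing_um=cfg.spacing_um)
        export_stack_slices(stack, cfg.output_dir / "stack")

    status = 1 if failures else 0
    return PipelineResult(status, series, summary, report_path, failures, maps)
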