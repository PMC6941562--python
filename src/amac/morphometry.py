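"""Infarct size, scar collagen content and remote interstitial fibrosis.

Per-section quantities are simple pixel-count ratios.  The study-level
infarct size is computed two ways, mirroring how serial-section studies
report it:

* the *average* infarct fraction — the unweighted arithmetic mean of the
  per-section percentages (the conventional estimate); and
* the *volumetric* infarct fraction

  .. math::

     S_\\text{infarct}\\,(\\%) =
        100 \\cdot \\frac{\\sum_i \\vartheta_i \\, n}{\\sum_i \\theta_i \\, n}

  where :math:`\\vartheta_i` is the infarcted area of section *i* in pixels,
  :math:`\\theta_i` its total heart area, and *n* the number of voxel slabs
  per section (pixels spanning the physical inter-section spacing, 300 µm by
  default).  With uniform *n* the weight cancels and the volumetric fraction
  reduces to :math:`100\\,\\Sigma\\vartheta / \\Sigma\\theta` — an area-weighted
  mean that down-weights small apical sections, which is why it generally
  differs from the unweighted average.

Sections without a scar or remote ROI carry ``None`` for those counts; such
missing values propagate to per-section percentages as ``None`` and are
skipped (never imputed as zero) when averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "SectionMeasurement",
    "SectionSeries",
    "SeriesSummary",
    "UndefinedMeasurementError",
    "infarct_fraction_section",
    "volumetric_infarct_fraction",
    "average_infarct_fraction",
    "collagen_content_pct",
    "interstitial_fibrosis_pct",
    "summarize_series",
]


class UndefinedMeasurementError(ValueError):
    """A ratio was requested from a section whose denominator is zero."""


def _check_count(name: str, v: int | None, allow_none: bool = False):
    if v is None:
        if allow_none:
            return None
        raise ValueError(f"{name} may not be None")
    v = int(v)
    if v < 0:
        raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    return v


@dataclass
class SectionMeasurement:
    """Pixel-count measurements for one serial section.

    Parameters
    ----------
    section_index
        1-based ordinal from the apex.
    infarct_area_px
        Infarcted (collagen-class) area of the whole section, in pixels.
    total_area_px
        Total heart tissue area of the section, in pixels.
    scar_collagen_px, scar_total_px
        Collagen and total tissue pixels inside the scar ROI, or ``None``
        when no scar ROI was delineated for this section.
    remote_fibrosis_px, remote_total_px
        Collagen-class (blue) and total tissue pixels inside the remote
        ROI; fine blue deposits between surviving fibers are the
        interstitial fibrosis signal.
    """

    section_index: int
    infarct_area_px: int
    total_area_px: int
    scar_collagen_px: int | None = None
    scar_total_px: int | None = None
    remote_fibrosis_px: int | None = None
    remote_total_px: int | None = None

    def __post_init__(self) -> None:
        self.section_index = int(self.section_index)
        self.infarct_area_px = _check_count("infarct_area_px", self.infarct_area_px)
        self.total_area_px = _check_count("total_area_px", self.total_area_px)
        if self.infarct_area_px > self.total_area_px:
            raise ValueError(
                f"infarct_area_px ({self.infarct_area_px}) exceeds "
                f"total_area_px ({self.total_area_px})"
            )
        for sub, tot in (("scar_collagen_px", "scar_total_px"),
                         ("remote_fibrosis_px", "remote_total_px")):
            sv = _check_count(sub, getattr(self, sub), allow_none=True)
            tv = _check_count(tot, getattr(self, tot), allow_none=True)
            setattr(self, sub, sv)
            setattr(self, tot, tv)
            if sv is not None and tv is not None and sv > tv:
                raise ValueError(f"{sub} ({sv}) exceeds {tot} ({tv})")


@dataclass
class SectionSeries:
    """An ordered series of serial sections with uniform physical spacing."""

    sections: list[SectionMeasurement]
    spacing_um: float = 300.0
    n_px_per_spacing: int = 1

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError(f"spacing_um must be > 0, got {self.spacing_um}")
        if self.n_px_per_spacing < 1:
            raise ValueError(
                f"n_px_per_spacing must be >= 1, got {self.n_px_per_spacing}"
            )
        idx = [m.section_index for m in self.sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"section_index must be strictly increasing, got {idx}"
            )


@dataclass
class SeriesSummary:
    """Study-level summary of a section series.

    Percentages are unrounded; reporting rounds half-even to two decimals.
    Optional averages are ``None`` when no section carries that ROI.
    """

    per_section_pct: list[float]
    average_infarct_pct: float
    volumetric_infarct_pct: float
    avg_collagen_pct: float | None = None
    avg_fibrosis_pct: float | None = None
    per_section_collagen_pct: list[float | None] = field(default_factory=list)
    per_section_fibrosis_pct: list[float | None] = field(default_factory=list)


def infarct_fraction_section(m: SectionMeasurement) -> float:
    """Infarct size of one section: 100 · infarct_area / total_area.

    Raises
    ------
    UndefinedMeasurementError
        If the section has zero total area.
    """
    if m.total_area_px == 0:
        raise UndefinedMeasurementError(
            f"section {m.section_index} has zero total area"
        )
    return 100.0 * m.infarct_area_px / m.total_area_px


def volumetric_infarct_fraction(s: SectionSeries) -> float:
    """Volumetric infarct size over the series (spacing-weighted).

    ``100 · Σ(infarct_px · n) / Σ(total_px · n)`` with *n* slabs per
    section; uniform *n* cancels, so the result is invariant to the choice
    of ``n_px_per_spacing``.

    Raises
    ------
    ValueError
        If the series is empty or no section has positive total area.
    """
    if not s.sections:
        raise ValueError("series contains no sections")
    n = s.n_px_per_spacing
    num = sum(m.infarct_area_px * n for m in s.sections)
    den = sum(m.total_area_px * n for m in s.sections)
    if den == 0:
        raise UndefinedMeasurementError("series has zero total area")
    return 100.0 * num / den


def average_infarct_fraction(s: SectionSeries) -> float:
    """Unweighted mean of the per-section infarct percentages."""
    if not s.sections:
        raise ValueError("series contains no sections")
    pcts = [infarct_fraction_section(m) for m in s.sections]
    return sum(pcts) / len(pcts)


def collagen_content_pct(m: SectionMeasurement) -> float | None:
    """Net collagen content of the scar: 100 · scar collagen / scar tissue.

    Returns ``None`` (not-available) when the section has no scar ROI;
    callers averaging over sections skip such values.
    """
    if m.scar_collagen_px is None or m.scar_total_px is None:
        return None
    if m.scar_total_px == 0:
        raise UndefinedMeasurementError(
            f"section {m.section_index} has an empty scar ROI"
        )
    return 100.0 * m.scar_collagen_px / m.scar_total_px


def interstitial_fibrosis_pct(m: SectionMeasurement) -> float | None:
    """Interstitial fibrosis in remote myocardium, as a tissue percentage.

    The numerator is collagen-class pixels inside the remote ROI, the
    denominator all tissue pixels in that ROI.  ``None`` when the section
    has no remote ROI.
    """
    if m.remote_fibrosis_px is None or m.remote_total_px is None:
        return None
    if m.remote_total_px == 0:
        raise UndefinedMeasurementError(
            f"section {m.section_index} has an empty remote ROI"
        )
    return 100.0 * m.remote_fibrosis_px / m.remote_total_px


def _mean_available(values: Sequence[float | None]) -> float | None:
    avail = [v for v in values if v is not None]
    return sum(avail) / len(avail) if avail else None


def summarize_series(s: SectionSeries) -> SeriesSummary:
    """Assemble per-section percentages and study-level averages.

    ROI averages run over sections with available values only; a section
    without a scar or remote ROI never contributes a zero.
    """
    if not s.sections:
        raise ValueError("series contains no sections")
    per_pct = [infarct_fraction_section(m) for m in s.sections]
    col = [collagen_content_pct(m) for m in s.sections]
    fib = [interstitial_fibrosis_pct(m) for m in s.sections]
    return SeriesSummary(
        per_section_pct=per_pct,
        average_infarct_pct=sum(per_pct) / len(per_pct),
        volumetric_infarct_pct=volumetric_infarct_fraction(s),
        avg_collagen_pct=_mean_available(col),
        avg_fibrosis_pct=_mean_available(fib),
        per_section_collagen_pct=col,
        per_section_fibrosis_pct=fib,
    )


def round_pct(value: float | None, ndigits: int = 2) -> float | None:
    """Round a percentage half-even for reporting; passes ``None`` through."""
    if value is None:
        return None
    # Decimal-correct banker's rounding (round() works on binary floats,
    # which matches half-even on the decimal representation closely enough
    # for 2-decimal percent reporting).
    return float(round(value, ndigits))
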