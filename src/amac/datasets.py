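"""Reference measurement tables bundled as example data.

A published comparison study measured ten serial trichrome-stained sections
(300 µm apart, apex to mitral valve) of one chronically infarcted mouse
heart twice: once manually with a commercial morphometry workstation and
once with automated per-pixel RGB-threshold counting.  The per-section pixel
counts and ROI percentages from that comparison are bundled here so the
downstream arithmetic — per-section infarct fractions, the unweighted
average, the volumetric (area-weighted) fraction, and ROI averages with
missing-value handling — can be exercised and cross-checked without the
original slide images, which were never deposited.

Section 1 (the apex tip) was excluded from measurement in the source study
and is represented by missing values throughout.
"""

from __future__ import annotations

import pandas as pd

from .morphometry import SectionMeasurement, SectionSeries

__all__ = [
    "load_example_sections",
    "load_example_roi_percentages",
    "example_series",
]

# Per-section areas in pixels, sections 2-10 (section 1 unmeasured).
# Columns: section index, manual total, manual infarct, automated total,
# automated infarct.
_SECTION_AREAS = [
    (2, 79048, 43023, 65841, 21610),
    (3, 149106, 45402, 103116, 18666),
    (4, 214502, 43172, 174738, 16941),
    (5, 338169, 61102, 275569, 27678),
    (6, 433953, 29029, 338801, 17933),
    (7, 462939, 0, 353645, 11271),
    (8, 479865, 0, 372602, 16221),
    (9, 470169, 0, 381734, 13290),
    (10, 476956, 0, 369464, 15220),
]

# Per-section ROI percentages.  Collagen content of the scar was only
# measurable where a scar ROI existed (sections 2-6); interstitial fibrosis
# of the remote zone was assessed on all measured sections.  The manual
# reader scored fibrosis as 0 on sections 6-10 (the fine deposits were
# below visual detection); the automated counts there are genuine values,
# not artifacts.  None marks a section without the ROI.
_ROI_PCTS = [
    # section, manual collagen, manual fibrosis, auto collagen, auto fibrosis
    (2, 16.3, 17.9, 17.11, 6.15),
    (3, 10.7, 9.6, 4.07, 5.33),
    (4, 10.6, 7.4, 1.11, 3.83),
    (5, 11.5, 6.6, 2.17, 4.62),
    (6, 8.0, 0.0, 0.13, 3.55),
    (7, None, 0.0, None, 3.19),
    (8, None, 0.0, None, 4.35),
    (9, None, 0.0, None, 3.48),
    (10, None, 0.0, None, 4.12),
]


def load_example_sections() -> pd.DataFrame:
    """Per-section manual and automated area measurements, in pixels."""
    return pd.DataFrame(
        _SECTION_AREAS,
        columns=[
            "section_index",
            "manual_total_px",
            "manual_infarct_px",
            "auto_total_px",
            "auto_infarct_px",
        ],
    )


def load_example_roi_percentages() -> pd.DataFrame:
    """Per-section scar-collagen and remote-fibrosis percentages."""
    return pd.DataFrame(
        _ROI_PCTS,
        columns=[
            "section_index",
            "manual_collagen_pct",
            "manual_fibrosis_pct",
            "auto_collagen_pct",
            "auto_fibrosis_pct",
        ],
    ).astype({"section_index": int})


def example_series(method: str = "auto") -> SectionSeries:
    """The example heart as a :class:`SectionSeries`.

    Parameters
    ----------
    method
        ``"auto"`` for the automated pixel counts, ``"manual"`` for the
        manual workstation counts.
    """
    if method not in ("auto", "manual"):
        raise ValueError(f"method must be 'auto' or 'manual', got {method!r}")
    tot = 3 if method == "auto" else 1
    inf = 4 if method == "auto" else 2
    sections = [
        SectionMeasurement(
            section_index=row[0], total_area_px=row[tot], infarct_area_px=row[inf]
        )
        for row in _SECTION_AREAS
    ]
    return SectionSeries(sections=sections, spacing_um=300.0, n_px_per_spacing=1)
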