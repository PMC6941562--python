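"""Synthetic trichrome-like sections with exact ground-truth class counts.

Real slides are rarely shareable, so the phantom paints what the classifier
must recognize: an annular left-ventricular wall in the red muscle palette,
a blue/blue-gray infarct wedge (the scar), sparse single-pixel blue
speckles in the remote wall (interstitial fibrosis), on a near-white
background.  Colors are drawn from palettes that sit strictly inside the
default class predicates, and a bounded per-channel hue jitter keeps them
there, so segmentation recovers the painter's own class counts *exactly* —
the ground truth is the rasterized label grid itself, counted during
painting, not an analytic approximation.

A series generator tapers the annulus and shrinks the wedge from apex to
base, mimicking how an infarct is large near the apex and absent near the
ligature, and returns per-section ground truth from which the true
volumetric infarct percentage is computable in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .segmentation import ColorClass

__all__ = ["PhantomSpec", "PhantomSection", "make_phantom_section",
           "make_phantom_series"]

# Palette anchors.  Collagen spans the blue-to-gray gradient; every
# interpolated color keeps B >= R + blue_margin(20) + jitter headroom, so
# the blue predicate holds after jitter up to MAX_SAFE_JITTER.
_COLLAGEN_ANCHORS = np.array([(30, 30, 200), (80, 80, 185), (140, 140, 170)],
                             dtype=float)
_MUSCLE_ANCHORS = np.array([(200, 40, 40), (220, 90, 90)], dtype=float)
_BACKGROUND_COLOR = (245, 245, 245)

#: Largest hue_jitter for which every palette color provably stays inside
#: its class predicate under the default thresholds.  Tightest margin: the
#: blue-gray anchor (140,140,170) has B-R = 30, which must stay >= 20 after
#: +j on R, -j on B and up to 1 intensity lost to rounding the interpolated
#: float color, so 30 - 2j - 1 >= 20 gives j <= 4 (background: 245-j >= 230).
MAX_SAFE_JITTER = 4


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, palette noise and seed for one synthetic section.

    Parameters
    ----------
    canvas
        (height, width) in pixels.
    outer_radius, inner_radius
        Annular wall radii in pixels; the lumen (inside ``inner_radius``)
        is background.
    infarct_angle
        Angular extent of the blue scar wedge, degrees in [0, 360].
    transmural
        If true the wedge spans the full wall thickness, else only the
        outer half (a non-transmural scar, the case that defeats
        midline-length sizing).
    fibrosis_density
        Per-muscle-pixel probability of a single-pixel blue speckle in the
        remote wall.
    hue_jitter
        Maximum per-channel color perturbation (uniform integer in
        [-j, +j]); must not exceed :data:`MAX_SAFE_JITTER`.
    seed
        Seed for all sampling; same seed, same image bytes.
    """

    canvas: tuple[int, int] = (256, 256)
    outer_radius: float = 100.0
    inner_radius: float = 55.0
    infarct_angle: float = 90.0
    transmural: bool = True
    fibrosis_density: float = 0.01
    hue_jitter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.canvas
        if h < 4 or w < 4:
            raise ValueError(f"canvas {self.canvas} too small")
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError(
                f"need 0 < inner_radius ({self.inner_radius}) < outer_radius "
                f"({self.outer_radius})"
            )
        if self.outer_radius > min(h, w) / 2:
            raise ValueError(
                f"outer_radius {self.outer_radius} exceeds half the canvas "
                f"{self.canvas}"
            )
        if not 0 <= self.infarct_angle <= 360:
            raise ValueError(f"infarct_angle {self.infarct_angle} not in [0, 360]")
        if not 0 <= self.fibrosis_density <= 1:
            raise ValueError(
                f"fibrosis_density {self.fibrosis_density} not in [0, 1]"
            )
        if not 0 <= self.hue_jitter <= MAX_SAFE_JITTER:
            raise ValueError(
                f"hue_jitter {self.hue_jitter} outside [0, {MAX_SAFE_JITTER}]; "
                "larger jitter could push colors out of their class"
            )


@dataclass
class PhantomSection:
    """One painted section with its ground truth."""

    image: np.ndarray                       # (H, W, 3) uint8
    counts: dict[ColorClass, int]           # painter's exact class counts
    scar_roi: np.ndarray                    # bool, the wedge region
    remote_roi: np.ndarray                  # bool, annulus minus wedge
    spec: PhantomSpec


def _interp_palette(anchors: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation along palette anchors, t in [0,1]."""
    n = len(anchors) - 1
    x = t * n
    i = np.minimum(x.astype(int), n - 1)
    frac = (x - i)[:, None]
    return anchors[i] * (1 - frac) + anchors[i + 1] * frac


def make_phantom_section(spec: PhantomSpec) -> PhantomSection:
    """Rasterize one annular phantom section.

    The wedge (scar ROI) is painted from the collagen palette, the rest of
    the wall (remote ROI) from the muscle palette with fibrosis speckles;
    class counts are taken from the painted label grid, so they are exact
    by construction.  Scar and remote ROIs partition the tissue.
    """
    h, w = spec.canvas
    rng = np.random.default_rng(spec.seed)
    cy, cx = (h - 1) / 2, (w - 1) / 2
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0

    annulus = (r >= spec.inner_radius) & (r <= spec.outer_radius)
    in_wedge_angle = theta < spec.infarct_angle
    if spec.transmural:
        wedge_radial = annulus
    else:
        mid = (spec.inner_radius + spec.outer_radius) / 2
        wedge_radial = annulus & (r >= mid)
    scar = wedge_radial & in_wedge_angle
    remote = annulus & ~scar

    labels = np.full((h, w), ColorClass.BACKGROUND, dtype=np.uint8)
    labels[remote] = ColorClass.MUSCLE
    labels[scar] = ColorClass.COLLAGEN

    # fibrosis speckles: single blue pixels over remote muscle
    if spec.fibrosis_density > 0:
        muscle_idx = np.flatnonzero(labels.ravel() == ColorClass.MUSCLE)
        speckle = muscle_idx[
            rng.random(muscle_idx.size) < spec.fibrosis_density
        ]
        labels.ravel()[speckle] = ColorClass.COLLAGEN

    image = np.empty((h, w, 3), dtype=float)
    image[...] = _BACKGROUND_COLOR
    for cls, anchors in ((ColorClass.COLLAGEN, _COLLAGEN_ANCHORS),
                         (ColorClass.MUSCLE, _MUSCLE_ANCHORS)):
        mask = labels == cls
        npx = int(mask.sum())
        if npx:
            image[mask] = _interp_palette(anchors, rng.random(npx))
    if spec.hue_jitter:
        image += rng.integers(-spec.hue_jitter, spec.hue_jitter + 1,
                              size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    binc = np.bincount(labels.ravel(), minlength=len(ColorClass))
    counts = {c: int(binc[c]) for c in ColorClass}
    return PhantomSection(image=image, counts=counts, scar_roi=scar,
                          remote_roi=remote, spec=spec)


def make_phantom_series(base: PhantomSpec, k: int,
                        taper: float = 0.0,
                        infarct_profile: Sequence[float] | None = None,
                        ) -> list[PhantomSection]:
    """Generate *k* serial phantom sections, apex to base.

    Parameters
    ----------
    base
        Spec for the first (apical) section.
    k
        Number of sections, >= 1.
    taper
        Outer- and inner-radius increment per section (positive values grow
        the heart toward the base, as serial sections do from the apex).
    infarct_profile
        Per-section wedge angles in degrees; defaults to a linear shrink
        from the base spec's angle to 0 (infarct largest near the apex).

    Each section gets an independent seed derived from ``base.seed``.  The
    true volumetric infarct percentage of the series is computable from the
    returned ground-truth counts.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if infarct_profile is None:
        infarct_profile = [base.infarct_angle * (1 - i / k) for i in range(k)]
    if len(infarct_profile) != k:
        raise ValueError(
            f"infarct_profile has {len(infarct_profile)} entries for k={k}"
        )
    sections = []
    for i in range(k):
        outer = base.outer_radius + taper * i
        inner = base.inner_radius + taper * i
        if not 0 < inner < outer or outer > min(base.canvas) / 2:
            raise ValueError(
                f"taper {taper} makes section {i + 1} radii invalid "
                f"(inner={inner}, outer={outer}, canvas={base.canvas})"
            )
        spec = replace(base, outer_radius=outer, inner_radius=inner,
                       infarct_angle=float(infarct_profile[i]),
                       seed=base.seed + 1000 * i)
        sections.append(make_phantom_section(spec))
    return sections


def series_ground_truth_volumetric_pct(sections: list[PhantomSection]) -> float:
    """True volumetric infarct percent from painter ground-truth counts."""
    col = sum(s.counts[ColorClass.COLLAGEN] for s in sections)
    tissue = sum(
        s.counts[ColorClass.COLLAGEN] + s.counts[ColorClass.MUSCLE]
        + s.counts[ColorClass.OTHER_TISSUE]
        for s in sections
    )
    if tissue == 0:
        return 0.0
    return 100.0 * col / tissue


__all__.append("series_ground_truth_volumetric_pct")
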