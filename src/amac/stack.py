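"""Assemble serial-section segmentations into a labeled voxel stack.

Each section's class map becomes ``z_step_px`` consecutive slabs (the
number of voxels spanning the 300 µm physical spacing), ordered apex to
base.  Sections are first padded onto a common canvas and translated so
their tissue centroids coincide — translation-only registration, which
preserves every per-class pixel count exactly, so volumetric percentages
read off the voxel stack agree with the series-level morphometry to the
last digit.  Slices export as transparent-background RGBA PNGs for external
3-D rendering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .segmentation import DISPLAY_COLORS, ColorClass, PixelClassMap

__all__ = [
    "VoxelStack",
    "align_sections",
    "build_stack",
    "stack_volume_summary",
    "export_stack_slices",
    "import_stack_slices",
]


@dataclass
class VoxelStack:
    """3-D label grid assembled from serial sections.

    ``labels`` has shape ``(depth, height, width)`` with
    ``depth == n_sections * z_step_px``; ``section_of_slab[k]`` is the
    source section index of slab *k*; ``offsets`` records the per-section
    (row, col) translation applied during alignment.
    """

    labels: np.ndarray
    z_step_px: int
    section_of_slab: list[int]
    offsets: list[tuple[int, int]]
    spacing_um: float = 300.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a (depth, H, W) grid")
        if len(self.section_of_slab) != self.labels.shape[0]:
            raise ValueError("section_of_slab length must equal stack depth")

    @property
    def depth(self) -> int:
        return self.labels.shape[0]

    def class_counts(self) -> dict[ColorClass, int]:
        binc = np.bincount(self.labels.ravel(), minlength=len(ColorClass))
        return {c: int(binc[c]) for c in ColorClass}


def _tissue_centroid(labels: np.ndarray) -> tuple[float, float] | None:
    rows, cols = np.nonzero(labels != ColorClass.BACKGROUND)
    if rows.size == 0:
        return None
    return float(rows.mean()), float(cols.mean())


def align_sections(maps: list[PixelClassMap],
                   canvas: tuple[int, int] | None = None,
                   margin: int = 8) -> tuple[list[PixelClassMap],
                                             list[tuple[int, int]],
                                             tuple[int, int]]:
    """Center each section's tissue centroid on a common canvas.

    The canvas defaults to the maximal section extent plus ``margin`` on
    each side; padding is background.  Translation is in whole pixels, so
    per-class counts are preserved exactly.  A section with no tissue at
    all is placed at offset (0, 0) with a warning.

    Returns the aligned maps, the per-section (row, col) offsets applied,
    and the canvas shape.
    """
    if not maps:
        raise ValueError("need at least one section to align")
    if canvas is None:
        h = max(m.height for m in maps) + 2 * margin
        w = max(m.width for m in maps) + 2 * margin
        canvas = (h, w)
    ch, cw = canvas
    aligned: list[PixelClassMap] = []
    offsets: list[tuple[int, int]] = []
    for i, m in enumerate(maps):
        if m.height > ch or m.width > cw:
            raise ValueError(
                f"section {i} ({m.height}x{m.width}) exceeds canvas {canvas}"
            )
        cen = _tissue_centroid(m.labels)
        if cen is None:
            warnings.warn(
                f"section {i} has no tissue pixels; using offset (0, 0)",
                stacklevel=2,
            )
            dr = dc = 0
        else:
            # shift that moves the tissue centroid onto the canvas center
            dr = int(round((ch - 1) / 2 - cen[0]))
            dc = int(round((cw - 1) / 2 - cen[1]))
        grid = np.full(canvas, ColorClass.BACKGROUND, dtype=np.uint8)
        # clamp so the section stays fully on canvas
        dr = min(max(dr, 0), ch - m.height)
        dc = min(max(dc, 0), cw - m.width)
        grid[dr:dr + m.height, dc:dc + m.width] = m.labels
        aligned.append(PixelClassMap(labels=grid))
        offsets.append((dr, dc))
    return aligned, offsets, canvas


def build_stack(maps: list[PixelClassMap], z_step_px: int = 1,
                section_indices: list[int] | None = None,
                offsets: list[tuple[int, int]] | None = None,
                spacing_um: float = 300.0) -> VoxelStack:
    """Replicate each aligned section into ``z_step_px`` consecutive slabs.

    Sections must share canvas dimensions (use :func:`align_sections`
    first); order is apex to base.

    Raises
    ------
    ValueError
        For an empty map list, mismatched canvas sizes, or z_step_px < 1.
    """
    if not maps:
        raise ValueError("need at least one section to build a stack")
    if z_step_px < 1:
        raise ValueError(f"z_step_px must be >= 1, got {z_step_px}")
    shape = maps[0].labels.shape
    for i, m in enumerate(maps):
        if m.labels.shape != shape:
            raise ValueError(
                f"section {i} shape {m.labels.shape} differs from {shape}; "
                "align sections onto a common canvas first"
            )
    if section_indices is None:
        section_indices = list(range(1, len(maps) + 1))
    labels = np.repeat(
        np.stack([m.labels for m in maps], axis=0), z_step_px, axis=0
    )
    section_of_slab = [s for s in section_indices for _ in range(z_step_px)]
    return VoxelStack(
        labels=labels,
        z_step_px=z_step_px,
        section_of_slab=section_of_slab,
        offsets=offsets or [(0, 0)] * len(maps),
        spacing_um=spacing_um,
    )


def stack_volume_summary(stack: VoxelStack) -> dict:
    """Per-class voxel counts and the volumetric infarct percentage.

    The infarct percentage is collagen voxels over tissue (non-background)
    voxels; because slab replication multiplies every section's counts by
    the same factor, it equals the series-level volumetric infarct fraction
    computed from per-section counts with uniform spacing.
    """
    counts = stack.class_counts()
    tissue = sum(v for c, v in counts.items() if c != ColorClass.BACKGROUND)
    if tissue == 0:
        pct = 0.0
    else:
        pct = 100.0 * counts[ColorClass.COLLAGEN] / tissue
    return {
        "voxel_counts": counts,
        "tissue_voxels": tissue,
        "volumetric_infarct_pct": pct,
    }


def _slice_to_rgba(slab: np.ndarray) -> np.ndarray:
    rgba = np.zeros(slab.shape + (4,), dtype=np.uint8)
    for cls in ColorClass:
        if cls is ColorClass.BACKGROUND:
            continue
        mask = slab == cls
        rgba[mask, :3] = DISPLAY_COLORS[cls]
        rgba[mask, 3] = 255
    return rgba


def export_stack_slices(stack: VoxelStack, directory: str | Path) -> list[Path]:
    """Write one transparent-background RGBA PNG per slab plus a JSON sidecar.

    Filenames encode the slab index (``slab_0000.png`` ...); the sidecar
    records z_step_px, spacing_um, per-section offsets and the slab-to-
    section mapping, enough to reimport the stack losslessly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(stack.depth):
        p = directory / f"slab_{k:04d}.png"
        iio.imwrite(p, _slice_to_rgba(stack.labels[k]))
        paths.append(p)
    sidecar = {
        "z_step_px": stack.z_step_px,
        "spacing_um": stack.spacing_um,
        "section_of_slab": stack.section_of_slab,
        "offsets": [list(o) for o in stack.offsets],
        "display_colors": {c.name: list(DISPLAY_COLORS[c]) for c in ColorClass},
    }
    with open(directory / "stack.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return paths


def import_stack_slices(directory: str | Path) -> VoxelStack:
    """Rebuild a :class:`VoxelStack` from an exported slice directory.

    Labels are recovered from the display colors: transparent pixels are
    background, opaque pixels map back through the class palette.
    """
    directory = Path(directory)
    with open(directory / "stack.json") as fh:
        sidecar = json.load(fh)
    color_to_class = {
        tuple(DISPLAY_COLORS[c]): c for c in ColorClass
        if c != ColorClass.BACKGROUND
    }
    slabs = []
    for p in sorted(directory.glob("slab_*.png")):
        rgba = iio.imread(p)
        slab = np.full(rgba.shape[:2], ColorClass.BACKGROUND, dtype=np.uint8)
        opaque = rgba[..., 3] > 0
        for color, cls in color_to_class.items():
            match = opaque & np.all(rgba[..., :3] == color, axis=-1)
            slab[match] = cls
        slabs.append(slab)
    return VoxelStack(
        labels=np.stack(slabs, axis=0),
        z_step_px=sidecar["z_step_px"],
        section_of_slab=sidecar["section_of_slab"],
        offsets=[tuple(o) for o in sidecar["offsets"]],
        spacing_um=sidecar["spacing_um"],
    )
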