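# Methods

## Pixel classification

A trichrome-stained section is segmented by evaluating four threshold
predicates on each pixel's 8-bit RGB (and optional alpha) values, in a
configurable precedence order with the first match winning:

1. **background** — `alpha == 0`, or `min(R, G, B) >= background_min_channel`
   (default 230). Fully transparent pixels are background regardless of
   color so that overlay images round-trip.
2. **collagen** — `B >= R + blue_margin` (default 20) and `B >= G`, *or*
   the pixel lies on the blue-to-gray gradient: channel spread
   `max − min <= gray_spread` (default 15) with every channel inside
   `[gray_low, gray_high]` (defaults 90, 200). Trichrome collagen fades
   from saturated blue in dense scar to blue-gray at the margins; the
   gray-band test captures the desaturated end without leaving RGB for a
   hue space.
3. **muscle** — `R >= B + red_margin` (default 20).
4. **other tissue** — any remaining pixel (stain transitions, nuclei,
   erythrocytes). It counts toward total tissue area but toward neither
   collagen nor muscle, because total heart area exceeds the sum of the
   clearly blue and clearly red areas on real sections.

All constants are on the 0–255 intensity scale and user-configurable (YAML
scheme files); the defaults are this package's own calibration of the
verbal blue/red/near-white scheme, chosen so that saturated blue
(30,30,200), blue-gray (140,140,170), red (200,40,40)–(220,90,90) and
near-white (245,245,245) — the canonical colors of the stain — classify
correctly with margin to spare. Default precedence is background >
collagen > muscle > other; permuting it changes only pixels satisfying two
or more predicates. No morphological cleanup is applied by default: the
method is raw pixel counting, and every reported number should be exactly
the count of matching pixels.

Classification operates in RGB only. Color deconvolution or stain
normalization would change counts in ways not auditable from thresholds,
and are out of scope.

## Morphometry

Per-section infarct size is `100 · ϑ/θ` with ϑ the collagen-class pixels
(of the whole section, or of the scar ROI when one is supplied) and θ the
tissue (non-background) pixels. The study-level size is reported two ways:

* the unweighted mean of per-section percentages (the conventional
  estimate), and
* the volumetric size `100 · Σ(ϑᵢ·n) / Σ(θᵢ·n)` with *n* slabs per
  section. Uniform *n* cancels, making the volumetric size the
  area-weighted mean of the per-section sizes; it is invariant to the
  choice of `n_px_per_spacing` and to section order. On the bundled
  example heart the two estimates differ by ~3.6 percentage points, the
  expected direction when apical sections are small but heavily infarcted.

Scar collagen content is collagen pixels over tissue pixels within the
scar ROI; interstitial fibrosis is collagen-class pixels over tissue
pixels within the remote ROI. The fibrosis *numerator* is deliberately the
blue (collagen) class: the remote zone is red muscle, and the fibrosis
signal is the fine blue deposits between fibers — the red tissue forms the
denominator, not the numerator. Sections without an ROI carry explicit
missing values that propagate to reports as `NA` and are skipped in
averages; a missing section never contributes a zero.

Percentages are kept at full precision internally and rounded half-even to
two decimals only at report time. Zero denominators raise an
`UndefinedMeasurementError` rather than returning 0 or NaN.

## 3-D reconstruction

Serial class maps are padded onto a common canvas (maximum section extent
plus an 8-pixel margin, padding class background) and translated in whole
pixels so each section's tissue centroid lands on the canvas center.
Registration is translation-only — no rotation, scaling or elastic
warping — which is the strongest transform that preserves every per-class
count exactly; it suffices for visual stacking and keeps the voxel-stack
volumetrics identical, not merely close, to the series-level morphometry.
A section with no tissue is placed at offset (0, 0) with a warning.

Each aligned section is replicated into `z_step_px` consecutive slabs
(voxels spanning the 300 µm physical spacing), apex to base. Slices export
as transparent-background RGBA PNGs plus a JSON sidecar (spacing, offsets,
slab-to-section map) from which the label stack re-imports losslessly.

## Synthetic phantoms

The phantom emulates what the classifier must recognize: an annular
left-ventricular wall (red palette, two anchors (200,40,40)–(220,90,90)),
a scar wedge of configurable angle spanning the full or outer-half wall
thickness (blue-to-gray palette, anchors (30,30,200), (80,80,185),
(140,140,170)), single-pixel blue speckles over remote muscle at a
configurable per-pixel probability (interstitial fibrosis), and a
(245,245,245) background. Geometry is integer-rasterized and ground truth
is counted from the painted label grid itself, so no rasterization
tolerance enters any comparison.

Per-channel hue jitter (uniform integers in ±j) is capped at j = 4: the
tightest palette margin is B−R = 30 at the blue-gray anchor, which must
stay ≥ 20 after opposing jitter on two channels plus up to one intensity
lost to rounding the interpolated float color. Within that cap,
segmentation recovers the ground-truth counts *exactly*, by construction —
the round trip is a correctness check of the classifier and pipeline
plumbing, not a statistical accuracy claim. What the phantoms do **not**
emulate: out-of-gamut staining variation, uneven illumination, compression
artifacts, tissue folds and debris. Passing the phantom suite therefore
validates the counting and arithmetic machinery, not the suitability of
the default thresholds for any particular scanner or staining batch; real
deployments should calibrate the scheme on their own slides.

Series phantoms taper the annulus toward the base and shrink the wedge
linearly (infarct largest at the apex), with per-section seeds derived
from the base seed so a series is reproducible from one integer.

## Example data

`amac.datasets` bundles the per-section pixel counts and ROI percentages
of one serially sectioned, chronically infarcted mouse heart measured both
manually and by automated counting (sections every 300 µm; the apex-tip
section was not measured and is represented as missing). The original
slide images were never deposited, so these counts are inputs: everything
downstream of counts — ratios, averages, volumetric weighting,
missing-value handling — is recomputed and checked against the published
summary values at their printed rounding (±0.05 for one/two-decimal
percentages, ±0.02 for ROI averages computed from already-rounded
per-section values).

## Numerical and design choices

* Tie-breaks: first matching predicate in precedence order; deterministic
  single-label output.
* Reports use a period decimal separator for machine readability; a
  locale flag can emit commas.
* Section order in batch runs is lexicographic on zero-padded filenames
  unless given explicitly.
* Per-section class counts are logged at INFO level so every report cell
  is auditable from the log; a failing section is recorded and the batch
  continues, with nonzero exit status.
* Problem sizes in the test and acceptance runs (256×256 phantoms, 100
  round-trip repetitions, 5-section series) were chosen as the smallest
  sizes at which wedge, speckles and taper all produce nondegenerate
  counts; the round trip is exact at any size.

## Known limitations

* RGB thresholds assume reasonably consistent staining; batches stained
  separately may need per-batch schemes (the stain itself drifts more
  than the camera).
* Translation-only alignment cannot correct rotation or tissue
  deformation between sections; the stack is for visualization and
  count-consistent volumetrics, not for shape-accurate meshing.
* 16-bit images are rejected rather than rescaled, since any rescaling
  choice would move pixels across thresholds silently.
* Whole-slide pyramid formats and machine-learned segmentation are out of
  scope.
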