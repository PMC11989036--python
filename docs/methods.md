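# Methods

## Problem and pipeline

The package quantifies CD117-positive interstitial cells of Cajal (ICCs)
in brightfield immunohistochemistry (IHC) scans. A slide is processed as:

1. read the RGB raster and resolve the physical pixel size;
2. compute a binary tissue mask;
3. tile the slide, run a detector per tile, map detections to the global
   frame and deduplicate;
4. count detections above a confidence threshold, convert the tissue mask
   to mm², and report the density in cells per mm² of tissue.

Detection quality is measured with the standard single-class detection
metrics (precision/recall/F1 at a confidence threshold, COCO-interpolated
AP at rotated-IoU thresholds 0.50–0.95).

## Oriented boxes and rotated IoU

A detection or annotation is an oriented rectangle (cx, cy, w, h, θ) in
continuous image coordinates (x right, y down, origin at the top-left
pixel corner). Since θ and θ+π describe the same rectangle, boxes are
canonicalised to w ≥ h and θ ∈ [−π/2, π/2), which makes equality and
round-trips testable. IoU of two boxes is computed exactly: each box
becomes a convex quadrilateral, the intersection is obtained by
Sutherland–Hodgman clipping, and areas come from the shoelace formula.
The degenerate zero-area-union case is defined as IoU 0. NMS is greedy in
descending score with ties broken by input index, so results are
deterministic across runs. The default NMS/dedup IoU threshold is 0.5,
matching the mAP50 convention; no published value exists for this
pipeline's inference stage, so it is a config knob.

## Tiling and seam handling

Tiles are `tile_size`² squares on a stride of `tile_size − overlap`; the
last tile per axis snaps back flush with the border rather than padding,
so detectors never see synthetic pixels. Tile counts per axis are 1 if the
image fits in one tile, else ⌈(dim − tile)/stride⌉ + 1.

Consolidation maps tile-local boxes to the global frame and runs one
oriented NMS pass over everything. NMS alone cannot remove the fragment
of a cell cut by a tile seam (the fragment's IoU with the whole-cell box
from the neighbouring tile is roughly the area ratio, far below any
sensible threshold), so before NMS any box that comes within
`edge_margin` pixels of an *interior* tile edge is dropped
(default `min(16, overlap // 2)`; edges flush with the image border are
exempt). This is sound whenever the tile overlap exceeds the largest
object extent plus twice the margin: every object then lies wholly inside,
and clear of the margin of, at least one tile. The default inference
overlap of 128 px comfortably exceeds the generator's largest cell
(~55 px soma plus processes). With these defaults, tiled detection and
whole-image detection returned identical counts on 20/20 synthetic
3000×2000 slides with 100 cells each.

## Stain model and the classical detector

Brightfield IHC follows Beer–Lambert absorption, so analysis happens in
optical density, OD = −log₁₀((I+1)/256) per channel. The H-DAB stain
basis is the Ruifrok–Johnston one (haematoxylin ≈ (0.65, 0.70, 0.29),
DAB ≈ (0.27, 0.57, 0.78), both unit-normalised, completed by their cross
product); stain concentrations are the OD vector times the inverse basis
matrix, with negative loadings clipped to zero. The basis is compiled in
and overridable per detector.

The `classical` detector thresholds the DAB OD map
(`dab_od_thresh`, default 0.15 OD), opens with a 1 px disk, labels
8-connected components, and keeps components with area in [30, 5000] px
and second-moment elongation ≥ 1.2 (ICCs are spindle-shaped; round nuclei
and specks are rejected). Box orientation comes from the principal axis
of the component's central second moments (with the +1/12 pixel-footprint
correction); side lengths are the pixel extents along the principal axes
plus 1 px. The confidence score is the component's mean DAB OD clipped at
1.0, so it is monotone in staining intensity and lives in [0, 1]. All
defaults were chosen against the synthetic generator and are not taken
from any published protocol; every one is exposed in the config.

The detector interface is a contract (`detect(image) -> boxes`), so a
trained oriented-box network can be registered by name and used by the
same pipeline; the classical baseline exists to keep the package
self-contained and to give the test suite a deterministic detector whose
behaviour on the generator is fully understood.

## Tissue mask, area and density

Glass is near-achromatic white while stained tissue is chromatic, so the
tissue mask thresholds saturation, (max−min)/max of RGB, at `sat_thresh`
(default 0.08), then applies closing (5 px), opening (3 px), hole filling
and removal of objects under 10,000 px. Physical area is
`n_pixels · (µm/px)² / 10⁶` mm²; an unknown pixel size is a hard error —
the package never assumes a scan resolution. Density is reported per mm²
of tissue (not per slide area). For slide batches the mean density gets a
Student-t interval, mean ± t₀.₉₇₅,ₙ₋₁·sd/√n; the hand example [1..5]
gives (1.0367, 4.9633) and Monte-Carlo calibration at n = 42 attains
95% ± 1% coverage.

The ANO1 semiquantitative score bins the positively stained fraction as
0 (none), 1 (up to 10%), 2 (over 10% up to 50%), 3 (over 50%); the
boundary between the printed "1–10%" and "11–50%" labels is closed by
treating the bins as half-open intervals (0, 0.10] and (0.10, 0.50].

## Evaluation

Matching is the usual detection protocol: predictions in descending
confidence each claim the unmatched ground-truth box of highest rotated
IoU if it reaches the threshold; every ground-truth box is matched at
most once. AP uses the 101-point COCO interpolation (monotone precision
envelope sampled at recalls 0.00…1.00), and mAP50–95 averages the ten
thresholds 0.50:0.05:0.95. Precision/recall at a fixed confidence uses
the same sweep restricted to the score prefix, which is exact because
greedy TP labels of higher-scored predictions do not depend on
lower-scored ones. Degenerate conventions: AP is undefined (reported
missing) without ground truth; with no predictions, precision is 1 when
there is also no ground truth and 0 otherwise. Whether published P/R
figures for detectors of this kind are quoted at a fixed confidence or at
the max-F1 point is generally ambiguous, so reports carry both. Batch
evaluation matches within each image and either pools TP/FP labels across
images for one global sweep (COCO-style, the default) or averages
per-image APs.

## Synthetic data generator

The generator emulates the features the pipeline is sensitive to, not
histological realism:

- **Tissue blob** — low-pass Gaussian noise thresholded at the
  (1 − tissue_fraction) quantile, giving a smooth random region whose
  pixel fraction hits the target essentially exactly; glass outside is
  near-white with faint achromatic haze (so it stays below the
  saturation threshold).
- **Cells** — elongated ellipse somata (long axis 28–55 px, aspect
  0.28–0.5, orientation uniform in [−π/2, π/2)) rendered as DAB OD
  0.6–0.9 with ±10% texture, plus 1–3 thin processes at 15% of the soma
  OD. The ground-truth box encloses the soma; processes extend past it,
  the way annotators box a cell body. Processes stain far below the
  detector threshold, reflecting that thin cytoplasm accumulates little
  chromogen — and meaning the detected blob is the soma the box
  describes.
- **Placement** — rejection sampling keeps every box (plus a 3 px margin)
  wholly inside the tissue, pairwise box IoU under 0.3, and distinct
  somata at least ~3 px apart (touching somata would fuse into one blob,
  which is not the situation being emulated). Over-dense requests fail
  with an explicit error after 10,000 attempts.
- **Distractors** — round-ish haematoxylin-only nuclei that a
  DAB-specific detector must ignore.
- **Rendering** — the OD maps are pushed through the same H-DAB basis the
  detector inverts, then quantised to uint8, so stain-level ground truth
  survives the round trip up to quantisation.

Everything derives from one integer seed (`numpy.random.default_rng`) and
is bit-reproducible. Defaults describe a well-stained slide at 0.5 µm/px
with moderate cell density — the regime in which a classical
intensity-based detector is a meaningful stand-in for a trained network.

What passing tests on this generator do **not** show: robustness to
staining variability across labs, to tissue folds, necrosis, vessels and
crypts, to out-of-focus regions, or to the full morphological variety of
real ICCs. A trained detector remains necessary for real slides; the
generator validates the *pipeline around* the detector (tiling, seam
handling, geometry, metrics, quantification) and the classical baseline's
parameter recovery under its own assumptions.

## Augmentation

The augmentation orbit is the 7 non-identity symmetries of the square
(rotations 90°/180°/270°, horizontal/vertical flips, both diagonal
flips). Box centres follow the exact affine coordinate map of each
symmetry; orientation follows the linear part applied to the box's long
axis, then re-canonicalisation (reflections reverse the sign of θ). Side
lengths are preserved exactly and every transform round-trips with its
group inverse to 1e-9. The dataset writer assigns the last
⌈val_fraction·n⌉ base images to an unaugmented validation split and
writes every training base with its 7 augmented copies (8 files per
base), with an index CSV recording file, seed, split and transform.
Augmentation multiplicity beyond the full D4 orbit is left as a
parameter of the surrounding training setup, which is out of scope here.

## Problem sizes used in the test suite

The end-to-end checks run at sizes chosen to exercise the real code paths
while keeping the suite quick on one CPU: 1024² tiles with 30 cells for
parameter recovery (20 seeds), 3000×2000 slides with 100 cells for stitch
consistency (20 seeds), 500 random box pairs against a 0.1 px
rasterization oracle for rotated IoU, 10,000 Monte-Carlo replicates for
CI coverage. Scaling any of these up is a matter of editing the test
constants; the underlying operations are size-agnostic.

## Known limitations

- The classical detector separates touching cells only via oriented NMS;
  genuinely overlapping ICCs in real tissue require a learned detector.
- Tissue masking by saturation assumes white-glass background; heavily
  pigmented or marker-drawn slides would need a different rule.
- TIFF reading is single-page baseline TIFF (plus PNG/JPEG); pyramidal
  vendor WSI formats are out of scope, as is out-of-core processing of
  slides larger than memory.
- Anisotropic pixel sizes are refused rather than resampled, because all
  area arithmetic assumes square pixels.
- The units of reported densities are only as good as the pixel-size
  metadata; the package refuses to guess when it is absent.
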