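# iccquant

Detection and quantification of **interstitial cells of Cajal (ICCs)** in
CD117-immunostained brightfield whole-slide images (WSIs).

ICCs are the pacemaker cells of the gut wall. In histopathology they are
identified by CD117 (c-kit) immunostaining: DAB chromogen renders them as
brown, spindle-shaped cells among smooth muscle, over a blue haematoxylin
counterstain. Counting them and normalising by tissue area gives an ICC
density (cells/mm²) that can be compared across specimens — but slides are
far too large to analyse at once, and manual counting does not scale.

`iccquant` provides the full quantification pipeline around a pluggable
cell detector:

- **Tiling** — fixed-size tiles on an overlapping grid with edge snap-back,
  so a detector only ever sees real pixels.
- **Oriented bounding boxes** — each cell is a rotated rectangle
  (cx, cy, w, h, θ); rotated IoU is computed analytically by convex polygon
  clipping, and duplicates across tile seams are removed by oriented
  non-maximum suppression (NMS) plus an interior-seam margin filter.
- **Detection** — a detector is anything with
  `detect(image) -> list[OrientedBox]`. The built-in `classical` baseline
  unmixes the H-DAB stains in optical-density space
  (OD = −log₁₀((I+1)/256), Ruifrok–Johnston basis), thresholds the DAB
  channel, and fits oriented boxes from second-order moments. A trained
  neural detector can be registered under a name and used unchanged.
- **Quantification** — saturation-based tissue masking, pixel→mm²
  conversion from TIFF resolution metadata (or an explicit µm/px override),
  density per mm² of tissue, and a Student-t 95% confidence interval for
  the mean density over a batch of slides. The semiquantitative ANO1
  membrane-expression score (0 / 1–10% / 11–50% / >50%) is included.
- **Evaluation** — greedy matching at rotated IoU, precision/recall/F1,
  and COCO-style 101-point average precision (mAP50, mAP50–95).
- **Synthetic data** — a generator of IHC-like images (DAB-brown ramified
  cells on haematoxylin-tinted tissue with glass margins) with known
  oriented-box ground truth, plus the full D4 rotation/flip augmentation
  orbit and a train/val dataset writer. Every stage of the pipeline is
  testable end to end without any external data.

## Worked example

Generate three synthetic 2048×2048 slides and quantify them:

```
$ python -c "
from iccquant.synthdata import SynthSpec, generate_image
from iccquant import imgio
for seed, (n, tf) in enumerate([(80, 0.72), (95, 0.65), (60, 0.70)]):
    img, gt, _ = generate_image(SynthSpec(seed=seed, width=2048, height=2048,
                                          n_cells=n, n_distractors=120,
                                          tissue_fraction=tf))
    imgio.write_image(img, f'slide{seed}.tif')
"
$ iccquant quantify slide0.tif slide1.tif slide2.tif --out out/
slide0.tif: 80 cells, 0.7672 mm^2 tissue, 104.28 cells/mm^2
slide1.tif: 95 cells, 0.6816 mm^2 tissue, 139.38 cells/mm^2
slide2.tif: 60 cells, 0.7340 mm^2 tissue, 81.74 cells/mm^2
mean density 95% CI: [36.3124, 180.6266] cells/mm^2
```

Each line reports the consolidated cell count at the configured confidence
threshold (default 0.25), the tissue area from the saturation mask at the
slide's pixel size (0.5 µm/px here, read from the TIFF tags), and their
quotient — the ICC density. The classical detector recovers the generator's
planted counts exactly (80, 95, 60). With two or more slides, the batch
report adds the t-interval for the mean density. `out/` receives, per
slide, an overlay PNG (boxes + tissue boundary), a JSON report with the
full configuration echo, and a combined CSV (one row per slide).

Other subcommands: `iccquant generate` (synthetic datasets with YOLO-OBB
labels), `iccquant tile`, `iccquant detect`, and `iccquant evaluate`
(`--pred-dir/--label-dir`, printing P/R/F1 at the chosen confidence, the
max-F1 point, mAP50 and mAP50–95).

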