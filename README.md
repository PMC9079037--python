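# neotherm

Camera fusion for contactless skin-temperature monitoring of neonates.

Preterm infants in intensive care are monitored with adhesive sensors that
can injure immature skin. A camera-based alternative combines an RGB camera
(where body landmarks can be detected reliably) with an infrared
thermography (IRT) camera (where each pixel is a surface temperature):
landmarks found in RGB are transferred into the thermogram and used to read
local skin temperatures. The clinically relevant output is the
**central-peripheral temperature difference (cpTD)** — mean skin temperature
over central body sites minus the mean over peripheral ones — an early
indicator of centralized circulation as seen in neonatal sepsis.

`neotherm` implements the full fusion pipeline and its evaluation
machinery, exercised end-to-end on synthetic multimodal phantoms with fully
known ground truth:

- **Registration** (`neotherm.registration`): the RGB→IRT mapping is a
  field-of-view crop plus an affine transform,
  `u = A (p − c) + t`, estimated by maximizing the mutual information

  `I(X,Y) = Σ_{x,y} p(x,y) log [ p(x,y) / (p(x) p(y)) ]`

  of the joint intensity histogram (64×64 bins, natural log) over a
  budgeted, seeded search (500 objective evaluations: principal-axes
  initialization, randomized global sampling, Nelder-Mead refinement).
- **Keypoints** (`neotherm.keypoints`): the 17 COCO person landmarks plus a
  neck derived as the shoulder midpoint; central/peripheral region
  classification; a seeded mock detector; OKS-based AP/AP75/AR evaluation;
  COCO keypoint JSON I/O.
- **Thermal** (`neotherm.thermal`): 16-bit centikelvin raster encoding,
  10×10 px ROI maximum extraction around each transformed landmark, cpTD,
  MAE/SD error statistics and Bland-Altman agreement analysis.
- **Phantom** (`neotherm.phantom`): a neonate-like capsule figure on a dark
  background with a closed-form temperature field — warm trunk/head,
  temperature falling along each limb — so registration accuracy and cpTD
  extraction can be validated against analytic truth.
- **Pipeline** (`neotherm.pipeline`): generate → detect → register →
  transform → extract → evaluate, deterministic under a single seed, with
  per-subject registration maps and CSV reports.

## Worked example

`examples/05_full_pipeline.py` runs six phantom subjects × five frames with
a noisy mock detector (5 px jitter, 10 % dropout) and ground-truth
registration maps:

```
frames: 30, undefined cpTD: 0
cpTD MAE vs labeled-keypoint reference: 0.118 C (SD 0.208 C)
point transfer MAE: x 2.25 px (1.13 mm), y 2.48 px (1.24 mm)
Bland-Altman: mean difference +0.051 C, limits of agreement [-0.408, +0.509] C
(a positive mean difference means the pipeline underestimates the reference cpTD)
```

Reading: every frame yielded a defined cpTD; detector noise propagated into
a mean absolute cpTD error of 0.12 °C against the reference computed from
labeled thermal keypoints; landmarks transferred with ≈2.4 px (≈1.2 mm at
the 0.5 mm/px clinical resolution) mean absolute error per axis; and the
slight positive Bland-Altman mean difference shows the window-maximum
extraction with imperfect keypoints tends to underestimate the reference
cpTD. The other scripts in `examples/` cover phantom generation,
registration recovery, keypoint evaluation, and the clothing scenario that
produces reduced or negative cpTD readings.

A thin CLI mirrors the library:

```bash
neotherm generate --out ds/ --pairs 3 --seed 0
neotherm register --rgb ds/rgb_0000.png --irt ds/irt_0000.tiff --out map.json --seed 0 --evals 500
neotherm extract --dataset ds/ --out cptd.csv
neotherm run-all --out run/ --subjects 3 --frames 5 --seed 0
```

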