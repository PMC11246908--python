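# lumbometry

Automatic measurement of lumbosacral radiographic parameters on lateral
lumbar radiographs: a multi-scale attention segmentation network labels the
five lumbar vertebral bodies and the sacrum, Harris corner detection on the
segmentation yields ten named anatomical key points, and four clinical
parameters are computed from them:

* **LL** — lumbar lordosis: angle between the superior endplates of L1 and S1
* **SHA** — sacral horizontal angle: S1 superior endplate vs the horizontal
* **ISA** — intervertebral space angle at L4–L5 and L5–S1 (signed; positive
  = the disc opens anteriorly)
* **PLS** — percentage of lumbar spondylolisthesis at L4–L5 and L5–S1
  (Taillard-style N/M × 100; positive = anterolisthesis)

Because clinical radiographs cannot ship with the package, a **phantom
module** generates synthetic standing-lateral-radiograph look-alikes (bright
vertebral quadrilaterals on a noisy gradient background) whose corner
landmarks are solved analytically so that the geometry module reproduces the
generating parameters exactly. Every pipeline stage is testable end-to-end
against this analytic ground truth.

The neural network is implemented on a small, fully tested numpy
reverse-mode autodiff engine (`lumbometry.segnet.autograd`) — no GPU or deep
learning framework is required; the scaled-down end-to-end run (100
phantoms, 30 epochs at 256×128) trains in a few minutes on one CPU.

## Layout

| module                 | contents |
|------------------------|----------|
| `lumbometry.geometry`  | key-point vocabulary, line/angle conventions, LL/SHA/ISA/PLS |
| `lumbometry.phantom`   | phantom spec sampling, analytic landmark solver, rendering, 8:1:1 datasets |
| `lumbometry.segnet`    | autograd engine, network blocks (Conv+BN+SiLU, Res-Attention, fusion, dilated module), training, inference |
| `lumbometry.keypoints` | connected regions → Harris corners → NMS → anatomical labels |
| `lumbometry.metrics`   | Dice / accuracy, PCK, observer reliability, ICC(2,1), agreement reports |
| `lumbometry.io`, `lumbometry.cli` | PNG/JPEG/minimal-DICOM, LabelMe JSON, CSV reports, CLI |

## CLI

```bash
# generate 100 synthetic phantoms (images, masks, LabelMe keypoints, manifest)
lumbometry phantom --n 100 --seed 0 --out data/

# train the segmentation network on them
lumbometry train --data data/ --out model/ --epochs 30 --seed 0

# segment an image
lumbometry predict --model model/model.npz --image data/images/phantom_00000.png --out pred/

# measure parameters from keypoints, a mask, or an image + model
lumbometry measure --keypoints data/keypoints/phantom_00000.json
lumbometry measure --mask pred/phantom_00000.png
lumbometry measure --image x.png --model model/model.npz

# compare prediction and reference folders (PCK / agreement / Dice tables)
lumbometry evaluate --pred pred_run/ --ref data/ --out report/
```

Exit codes: `0` success, `1` usage error, `2` data/anatomy error. Every run
writes a `run.json` with its resolved configuration, config hash and library
versions.

File dialects: masks are 8-bit PNG label maps (0 background, 1 lumbar,
2 sacrum); keypoints are LabelMe-style JSON (point shapes labelled `L1SA`,
`L1SP`, `L4IA`, `L4IP`, `L5SA`, `L5SP`, `L5IA`, `L5IP`, `S1SA`, `S1SP`) or
`name,x,y` CSV, always in pixel units; parameter sets are JSON/CSV with the
fixed column order `LL,SHA,ISA_L4L5,ISA_L5S1,PLS_L4L5,PLS_L5S1`. DICOM
support is a minimal explicit-VR little-endian single-frame reader/writer
that honours `PixelSpacing`.

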