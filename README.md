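# rootarm

Lightweight automatic root-length measurement for seed-germination imaging:
instance-segmentation post-processing that turns root masks into physical
lengths, plus the two compression techniques — channel-wise feature
distillation and batch-norm-scale structured pruning — that make the
segmentation backbone small enough for low-cost deployment, with the
matching evaluation (mask mAP@0.5) and analytic complexity accounting
(FLOPs, parameters, weight-file size, FPS).

## Who this is for

Plant-phenotyping groups measuring primary-root growth of germinating seeds
(e.g. pea on filter paper in petri dishes, imaged top-down at fixed scale)
who want an automated replacement for manual ruler measurements, and anyone
who needs the compression/evaluation machinery for a compact segmentation
network on a CPU-class device.

## The method

**Geometry.** Each predicted root mask is reduced to the closed outer
contour of its 8-connected foreground region (Moore border following,
clockwise, row 0 at top). With contour pixels k_1 … k_n and k_0 ≡ k_n, the
pixel perimeter is

    S_p = Σ_{m=1..n} |k_m − k_{m−1}|          (Euclidean steps)
    S_r = S_p / r                             (r = pixels per mm, default 7)
    L   = S_r / 2                             (half-perimeter rule)

A thin elongated root's outer contour runs down one side and back up the
other, so halving the perimeter cancels the doubling and L estimates the
root's arc length. Seeds are segmented jointly with roots (it sharpens the
seed–root boundary) but never measured.

**Distillation.** A frozen teacher and a smaller student expose feature
maps at paired layers. Each channel is softened into a distribution over
its N = W·H spatial positions by a temperature-T softmax φ, and the student
minimises

    Loss_CWD = (T²/C) Σ_c Σ_i φ(y^T_{c,i}) · log[φ(y^T_{c,i}) / φ(y^S_{c,i})]
    Loss_Distillation = Loss_Segment + α·Loss_CWD        (α = 1)

with a learnable 1×1 convolution adapting student channels to the
teacher's when widths differ.

**Pruning.** Batch-norm scales γ gate channel importance. Sparsity training
adds λ·Σ|γ| to the segmentation loss; channels whose |γ| falls below a
global quantile threshold are physically sliced out of the network
(producer rows, consumer columns, BN vectors), protected layers and
residual-coupled groups handled structurally; a short fine-tune recovers
accuracy; the cycle repeats at ~10% per iteration.

**Accounting.** FLOPs(Conv) = 2·H·W·(C_in·K²+1)·C_out on the output grid,
Params(Conv) = C_in·K²·C_out (+2·C_out for BN, +C_out for bias),
FLOPs(FC) = 2·n_in·n_out + n_out, weight file = 4 bytes/param, and
FPS = 1000 / total per-frame milliseconds.

No real dataset ships with the package: `rootarm.synthgerm` generates
seeded germination scenes with exactly known root arc lengths, and
`rootarm.backbone.TinySegNet` is a CPU-trainable encoder–decoder that
stands in for a production backbone behind the same adapter contract.

## Worked example

```python
import numpy as np
from rootarm.maskgeom import BinaryMask, Calibration, measure_instance_mask

mask = np.zeros((5, 80), dtype=bool)
mask[2, 3:74] = True                      # a 1-px root, 71 pixels long
m = measure_instance_mask(BinaryMask(mask), Calibration(7.0))
print(f"S_p = {m.perimeter_px:.1f} px, S_r = {m.perimeter_mm:.2f} mm, "
      f"L = {m.length_mm:.2f} mm")
```

prints

    S_p = 140.0 px, S_r = 20.00 mm, L = 10.00 mm

— the contour traverses the 70-step run twice (140 px), which is 20 mm at
7 px/mm, and the half-perimeter rule reports a 10 mm root.

The command line mirrors the library:

```bash
rootarm synth --n-scenes 4 --seed 1 --out scenes/     # synthetic dataset
rootarm measure --masks scenes/annotations.json --r 7 --out lengths.csv
rootarm complexity                                     # bundled architecture
rootarm timeseries --seed 1 --out drought.csv          # reporting demo
```

`rootarm complexity` prints

    yolov8-seg-n-2class-640: Params 3.26 M | FLOPs 12.0 G | weight 12.45 MB (fp32) / 6.23 MB (fp16)

for the bundled two-class n-scale single-stage segmentation architecture at
640×640.

## Layout

| module | role |
|---|---|
| `rootarm.maskgeom` | contours, perimeter, calibration, root length |
| `rootarm.metrics` | mask IoU, matching, PR curves, AP, mAP@0.5 |
| `rootarm.distill` | channel-wise KL distillation and adapters |
| `rootarm.pruning` | BN-γ sparsity, thresholding, plan, surgery, iteration |
| `rootarm.complexity` | analytic FLOPs/Params/weight/FPS from layer specs |
| `rootarm.synthgerm` | synthetic scenes, augmentation, split, annotation I/O |
| `rootarm.backbone` | backbone contract, TinySegNet, plug-in registry |
| `rootarm.nn`, `rootarm.train` | numpy layer kernels and training loops |
| `rootarm.timeseries`, `rootarm.cli` | growth-curve reporting and the CLI |

See `docs/methods.md` for modelling assumptions, parameter defaults, known
biases and limitations.
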