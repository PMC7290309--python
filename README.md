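# octava

**OCT angiography en face image enhancement and microvascular
quantification.**

Single-shot en face OCT angiography (OCTA) images of the retinal
superficial capillary plexus are noisy: speckle and flow-decorrelation
noise fragment capillaries and fill the foveal avascular zone (FAZ) with
false signal. The classical remedy — registering and averaging ~10 repeat
acquisitions — produces clean images but multiplies acquisition time.
`octava` implements the deep-learning alternative end to end: the
registered multi-frame average is used as a *teacher* to train a U-Net
denoiser on (single shot, average) patch pairs, after which a single shot
suffices. Because clinical OCTA data cannot ship with a package, `octava`
includes a full synthetic-eye simulator (branching vasculature with a FAZ,
speckle, background noise, dropout, inter-frame jitter, shadow/motion-line
artifacts) so the entire method and its evaluation run from scratch with
known ground truth.

It is aimed at researchers studying OCTA image enhancement and at anyone
needing reference implementations of the standard OCTA quantification
chain.

## Core quantities

For each image class — **original** (first single shot), **averaged**
(registered mean of n = 10 frames), **denoised** (network output on the
original) — the package computes:

* **CNR** = (f − b)/√(δf² + δb²), with f, δf over four corner discs
  (diameter 20 px, pooled) and b, δb over a FAZ disc;
* **PSNR** = 10·log₁₀(255²/MSE) against the averaged image as reference;
* **VD** — vessel-pixel fraction of the binarized image;
* **VLD** — skeleton length per unit area (mm⁻¹);
* **VDI** — vessel area / skeleton length (mean caliber, px);
* **FD** — box-counting fractal dimension of the skeleton, in [0, 2];

and compares the three groups with one-way ANOVA + Tukey HSD (paired
t-test for PSNR), reporting mean ± SD per group.

## Worked example

```python
from octava import (ExperimentConfig, run_experiment)

table, report, model = run_experiment(ExperimentConfig(seed=1))
print(table.groupby("label")[["cnr", "psnr_db", "vld_per_mm", "vdi_px", "fd"]].mean())
```

which prints (≈3 min on one CPU core):

```
               cnr    psnr_db  vld_per_mm    vdi_px        fd
label
averaged  0.859034        NaN   11.255750  4.769491  1.411031
denoised  0.655196  18.275724   10.262309  4.719940  1.387384
original  0.477565  13.819842   12.205445  4.359892  1.447535
```

Reading: denoising the single shot raises its CNR (0.48 → 0.66) and its
PSNR against the averaged reference (13.8 → 18.3 dB) — the denoised image
looks like an average while costing one acquisition. The vascular metrics
shift the way noise removal should shift them: spurious skeleton fragments
from background specks disappear (VLD 12.2 → 10.3 mm⁻¹, FD 1.45 → 1.39)
and vessels stop being fragmented into thin shards (VDI 4.36 → 4.72 px),
while VD stays in a narrow band across all three images (noise pickup and
vessel dropout offset each other in the original). `report` carries the
ANOVA/Tukey and paired-t statistics for these comparisons.

The same pipeline is scriptable from the shell:

```sh
octava simulate --n-eyes 3 --n-frames 10 --seed 7 --out scratch/eyes
octava average --frames scratch/eyes/eye000 --out scratch/avg.png
octava train --data scratch/eyes --out scratch/model.npz
octava denoise --model scratch/model.npz --in scratch/eyes/eye000/frame00.png --out scratch/den.png
octava vessels --image scratch/den.png --resample-500 --out scratch/metrics.json
octava experiment --seed 1 --out scratch/exp
```

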