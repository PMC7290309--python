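# Methods

## Problem and pipeline

Single-shot en face OCT angiography (OCTA) images are dominated by speckle
and decorrelation noise; averaging ~10 registered repeat acquisitions gives
a much cleaner image at the cost of a long acquisition. `octava` implements
and evaluates the deep-learning alternative: treat the registered
multi-frame average as a free supervision signal, train an encoder–decoder
network on (single shot, average) patch pairs of the same eye, and apply it
to a single shot. The package covers the whole loop on synthetic data with
known ground truth: simulation of repeated acquisitions, registration and
averaging, denoiser training and inference, and the quantitative readouts
used to compare the three image classes (original = first frame, averaged,
denoised): CNR, PSNR versus the average, and the vascular metrics VD, VLD,
VDI and box-counting FD computed from binarized and skeletonized images.

## Synthetic eye model

`synthdata` generates a ground-truth vasculature as stochastic branching
trees grown from the field perimeter toward a central foveal avascular zone
(FAZ, default radius 0.25 mm) on a 232 × 232 grid covering 3 × 3 mm
(`mm_per_pixel = 3/232`). Trees random-walk with direction noise
(`turn_sigma = 0.16` rad/step), taper along their length, and branch with
probability 0.045/step; radii start at 2.6 px and may not fall below
0.5 px. The clean render stamps anti-aliased discs along each centerline
(vessel intensity 0.85 of full scale) over a faint smoothed capillary-bed
texture (0.12); the FAZ interior is exactly zero.

Each simulated acquisition degrades the clean render with, in order:

1. **Flow-decorrelation dropout** — with probability 0.25 per segment, a
   geometric-length run of the centerline is attenuated to near zero.
2. **Scene translation** — integer jitter drawn uniformly from
   [−3, +3]² px per frame (frame 0 fixed at (0,0)).
3. **Multiplicative speckle** — mean-1 gamma field, shape 3.
4. **Additive background noise** — folded normal, scale 0.32 × 255.
5. Optional focal **shadow** attenuation and a **motion-line** row gain.

Speckle and background fields are smoothed to a correlation length of
0.8 px and rescaled to preserve their marginal moments. The grain matters:
coherent-imaging noise has finite speckle size, and only spatially
correlated specks survive the 3 × 3 median prefilter of the binarization
step to register as false "flow" in single-shot masks. The noise scales
were calibrated so that, as in real single shots, false-flow pickup in
avascular regions roughly offsets speckle-induced vessel dropout — the
mechanism that leaves vessel density (VD) nearly unchanged across
original/averaged/denoised images while VLD, VDI, and FD shift. The
defaults are fixed; they are not matched to any clinical cohort's metric
magnitudes.

What the simulator does **not** model: physically accurate OCT speckle
statistics, 3-D volumes and projection artifacts from deeper plexuses,
rotational or deformable eye motion, A-scan-level artifacts. Passing tests
therefore demonstrate the pipeline's internal correctness and the
qualitative behavior of the method under a plausible noise model, not
clinical performance.

## Registration and averaging

`enhance_average` registers each frame to frame 0 by exhaustive search over
integer translations within ±`max_shift` (default 10 px), maximizing
normalized cross-correlation over the overlap. Frames with peak correlation
below 0.2 are excluded, modelling acquisitions that fail to register.
The average is the per-pixel arithmetic mean over the frames that cover
each pixel after re-alignment (no cropping), so output dimensions match the
input — required for pixelwise PSNR. Noiseless shifted frames are recovered
exactly; with additive noise of variance σ² the FAZ-region variance after
10-frame averaging is σ²(1 − 2/π)/10 (folded-normal variance over n).

## Denoiser

A U-Net–family encoder–decoder, implemented directly on numpy arrays with
hand-written forward/backward passes (im2col + BLAS matmuls; gradients
verified against finite differences in the test suite). Per scale: two 3 × 3
same-padding convolutions + ReLU; 2 × 2 average pooling down; nearest-
neighbor upsampling and skip concatenation up; linear 1 × 1 output head.
Training minimizes pixelwise L1 (default; L2 available) between
`net(single-shot patch)` and the registered average patch of the same eye
at the same origin, with Adam (lr 2 × 10⁻³) on minibatches of 16. All
randomness derives from the config seed; runs are bit-reproducible, and
checkpoints (single `.npz` with weights + config JSON + format version)
reload to pixel-identical inference.

Config defaults are depth 3, 16 base channels, 64-px patches at stride 32.
The cohort experiment uses a lighter instance (8 channels, 32-px patches at
stride 16, 800 steps — ≈2 min on one CPU core) chosen as the package's
desk-scale default; on the synthetic cohort it is fully converged in the
sense that all qualitative effects are stable across seeds. Inference tiles
the full image with 50%-overlapping patches and uniform blending.

The teacher is the registered average of the *same* eye — pairs are never
mixed across eyes. The network regresses teacher intensities (a regression
reading of the encoder–decoder; no pixel classification is involved).

## Quality metrics

* **CNR** uses one background disc (diameter 20 px) at the FAZ center and
  four foreground discs inset 4 px from the corners;
  CNR = (f − b)/√(δf² + δb²) with foreground statistics pooled over the
  four discs as one pixel set. Discs rasterize as pixels whose centers lie
  within the radius (ties included); a diameter-20 disc covers 317 px
  (continuous area ≈ 314 px²). The same ROI set is placed once per eye and
  reused across its three images.
* **PSNR** = 10·log₁₀(255²/MSE) against the averaged image as reference;
  MSE = 0 yields a +∞ sentinel, never an error.

## Vascular metrics

Binarization: optional nearest-neighbor resample to the 500 × 500 export
grid (the device-software convention; the physical field is preserved, so
`mm_per_pixel` rescales), then a 3 × 3 median prefilter and a global Otsu
threshold (default; local-mean and fixed thresholds available).
Skeletonization is topology-preserving thinning (scikit-image).

* **VD** — vessel-pixel fraction of the mask.
* **VLD** — skeleton length / field area (mm⁻¹). Length sums 8-neighbor
  steps: 1 per orthogonal step, √2 per diagonal step, with a diagonal pair
  skipped when the two pixels share a 4-connected skeleton neighbor (the
  path already runs through it), so staircase paths are not double-counted;
  isolated pixels count 1.
* **VDI** — mask area / skeleton length (px); error on empty skeletons.
* **FD** — box counting on the skeleton with box sizes 2, 4, 8, … up to
  min(dim)/4 on a single origin-anchored grid; FD is the least-squares
  slope of log N(s) versus log(1/s), clamped to [0, 2] with a warning.
  Fewer than three usable sizes is an error; an empty skeleton returns 0
  with a warning.

Numerical conventions fixed throughout: (row, col) 0-based indexing, pixel
centers at integer coordinates, population SDs (ddof 0) inside CNR, sample
SDs (ddof 1) in cohort summaries, 8-bit quantization by round-half-even.

## Cohort experiment and statistics

`run_experiment` simulates disjoint training and test cohorts (seeds from
separate spawned streams; defaults 20 training and 10 test eyes, 10 frames
each), trains the denoiser on the training cohort's (frame 0, average)
pairs, and evaluates the test cohort's image triplets. Metrics are compared
with the scheme standard for three-way image comparisons in OCTA
research: one-way ANOVA + Tukey HSD across the
three groups for CNR/VD/VLD/VDI/FD, and a paired t-test for PSNR (defined
only for original and denoised, both against the averaged reference).
Identical groups are reported as p = 1 by convention.

At these problem sizes the full experiment runs in ≈3 minutes on one CPU
core. Expected qualitative outcome, reproduced at multiple seeds: denoised
images beat originals on CNR and PSNR; VLD and FD drop and VDI rises after
denoising; the three VD means stay within 20% of one another.

## Known limitations

* The denoiser is desk-scale; it demonstrates the method, not a clinical
  model, and its absolute metric values depend on the synthetic noise
  model.
* Registration is integer-translation only by design; rotations or
  within-frame distortions are out of scope.
* Binarization/skeletonization algorithms of commercial devices are
  unpublished; the defaults here are declared, configurable choices, and
  all qualitative findings are reported under those defaults.
* Artifact phenomena (focal shadow, motion lines) are simulated as input
  perturbations; automatic artifact detection is not implemented.
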