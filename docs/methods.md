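# Methods

## Pipeline overview

The package implements a three-stage virtual H&E staining workflow:

1. **Preprocessing** — foreground segmentation by adaptive mean
   thresholding, SIFT/RANSAC homography registration of the unstained
   slide onto the stained frame, overlapping patch extraction, and
   removal of background-only patches.
2. **Training** — dual contrastive GAN: generators G1: A→B and G2: B→A,
   patch discriminators D_A/D_B, and per-domain two-layer projection
   heads H_A/H_B supplying embeddings for the patchwise contrastive loss.
3. **Inference** — tile a whole slide at 50% overlap, translate each tile
   with G1, and alpha-blend with a partition-of-unity weight window.

Evaluation uses the Fréchet distance between Gaussian fits of per-image
feature vectors (FID) and the subset-averaged unbiased squared MMD under
the cubic polynomial kernel k(x,y) = (xᵀy/d + 1)³ (KID).

## Model and objective

Images live in [−1, 1], NHWC. The generator is a residual encoder–decoder
(stem conv → strided downsampling convs → residual blocks → nearest-
neighbor upsampling convs → tanh output); the discriminator is a strided
patch classifier emitting a spatial realness map. Encoder tap layers for
the contrastive loss default to: the input image, the stem, every
downsampling conv, and the middle residual block. Each tap layer has its
own two-layer MLP inside H_A/H_B producing L2-normalized K-vectors;
A-side features always pass through H_A and B-side features through H_B,
so the two domains keep separate embeddings.

Per training step: both discriminators are updated on detached
translations first (non-saturating log-form adversarial loss by default;
least-squares form by config), then G1, G2, H_A, H_B are updated jointly
against

λ_GAN (ℒ_GAN1 + ℒ_GAN2) + λ_NCE (ℒ_PatchNCE_A + ℒ_PatchNCE_B) + λ_idt ℒ_idt

with λ_GAN = 1, λ_NCE = 2, λ_idt = 1. The contrastive term is an
(N+1)-way cross entropy over cosine similarities at temperature τ,
computed with a log-sum-exp formulation that stays finite down to
τ = 0.01. Reductions are means over layers, locations and batch; the two
identity terms are summed. The displayed losses are expectations; means
are the natural estimator.

### Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| τ (temperature) | 0.07 | similarity scale in the contrastive softmax; standard contrastive-translation practice |
| λ_GAN, λ_NCE, λ_idt | 1, 2, 1 | relative loss weights of the collective objective |
| S_l (locations/layer) | 256 (full), 64 (tiny) | patches contrasted per layer |
| K (embedding dim) | 256 (full), 32 (tiny) | projection-head output size |
| optimizer | Adam, lr 2·10⁻⁴, β = (0.5, 0.999) | standard GAN regime |
| patch/stride (preprocess) | 512 / 256 px | training tile geometry |
| blank-patch cutoff | foreground fraction < 0.05 | discards background tiles |
| Lowe ratio / RANSAC tol | 0.75 / 3 px | SIFT match filtering and inlier band |
| adversarial form | log (non-saturating) | printed cross-entropy form; `lsgan` available by config |

The `tiny` preset (base 8 channels, 1 downsample, 2 residual blocks,
3×3 stem/output kernels, K = 32, S_l = 64) exists so the full training
loop runs in minutes on one CPU core; the `full` preset keeps the
reference-scale architecture (base 64, 2 downsamples, 9 blocks, 7×7
stem). Desk-scale studies here use 64×64 patches and about 1000
iterations at batch size 1 — small enough to iterate quickly, large
enough for the translation to converge on the synthetic task.

Training is deliberately **unpaired**: the unstained and stained patch
pools are shuffled independently, so the model never sees pixel
correspondences even though the synthetic fixtures are aligned. No data
augmentation is applied, matching the practice of keeping tissue in its
reading orientation.

## Numerical engine

No GPU tensor library is assumed; the networks run on a small reverse-
mode autodiff engine over numpy (`virtstain.autodiff`) with im2col-based
convolutions, a fused instance-norm primitive, and a log-sum-exp
primitive. All training math stays in float32 (binary operations treat
python scalars with numpy's weak promotion so constants never upcast the
graph); oracle tests run the same code in float64. Gradients of every
primitive are checked against central finite differences in the test
suite. Checkpoints store all six component weight sets, both Adam states,
and the exact RNG state, so a restored run continues bit-identically.

## Registration

SIFT keypoints are detected on contrast-stretched grayscale; matches pass
a 0.75 ratio test with cross-checking; a projective transform is fitted
by RANSAC with a 3 px reprojection tolerance (at least 4 surviving
matches required, else a registration failure names the pair). The
unstained image is warped into the stained frame, per the workflow's
registration direction. On synthetic pairs with known homographies
(rotations up to 5°, shifts up to 20 px, mild projective terms), the
median mean-corner reprojection error is well under 1 px. Elastic or
nonlinear deformation is out of scope.

## Tiling and blending

Tiles are half-open [r, r+P) × [c, c+P) windows, row-major, 0-based, with
reflect padding up to the tiling lattice so every pixel is covered. At
inference the stride is P/2, so each interior pixel is covered by exactly
4 tiles. The blend window is a separable **tent**: each 1-D profile ramps
linearly over each half-tile ((i+0.5)/(P/2) on the leading half, mirrored
on the trailing half), with sides on the canvas boundary clamped to 1.
Adjacent tents sum to exactly 1 at every sample, making the partition of
unity exact in floating point; a plateau-plus-ramp window cannot achieve
this at 50% overlap, because every pixel lies in an overlap region of two
tiles per axis. This yields the corner/edge/interior weight distinction:
corner tiles keep weight 1 in their outer corner, edge tiles along their
boundary side. Accumulation is in float with one final rounding, so
stitching untouched crops reproduces the slide to ≤ 1 intensity level.

## Metrics

FID fits (μ, Σ) to each feature cloud and evaluates
‖μ_a−μ_b‖² + tr(Σ_a + Σ_b − 2(Σ_a Σ_b)^{1/2}), with 10⁻⁶ diagonal jitter
before the matrix square root and imaginary-part stripping after. KID is
the unbiased MMD² estimator averaged over seeded subsets (defaults:
subset size 100, 10 subsets; null-calibration measurements use larger
subsets — 500×20 — so estimator noise, about 0.03 per size-100 subset on
16-d Gaussians, stays far below the 0.01 band being checked).

The production feature extractor in this literature is Inception-v3
pool3 (2048-d, inputs resized to 299×299); since pretrained weights
cannot be assumed, extractors are pluggable and the default is a
deterministic random-projection extractor (resize to 24×24, project
pixels and gradient magnitudes through a fixed seeded Gaussian matrix,
d = 64). It is bit-reproducible, needs no downloads, and is sensitive to
the color/texture differences that matter here; absolute FID/KID values
under it are **not** comparable to Inception-based numbers, only
orderings and relative changes are used.

## Synthetic fixtures: what they emulate and what they don't

`virtstain.fixtures` builds paired canvases: cytoplasm blobs from
thresholded smoothed noise covering a requested area fraction; elliptical
nuclei from a homogeneous Poisson process (density per 10⁴ px², radii
3–6 px); an "unstained" rendering that compresses optical density into
the 200–255 luminance band plus Gaussian noise (faint brightfield
contrast); and a stain oracle that multiplies a class color (blue-purple
nuclei, pink cytoplasm, near-white background) by a shade derived from
local density — multiplicative shading preserves hue within each class —
then softens class edges with a small Gaussian. Misalignment is applied
to the unstained member as a known random homography stored in the
manifest.

The stain mapping is locally decidable from texture and class, which is
exactly the property a patch-level translator can learn; passing the
learnability check therefore shows the training loop optimizes the right
objective, **not** that the model reaches diagnostic quality on real
slides. The fixtures have no out-of-focus regions, staining artifacts,
batch-to-batch color variation, or elastic deformation; nuclei may
overlap tissue boundaries; and segmentation block sizes must be chosen
relative to the ~25 px structure scale (the fraction-recovery test uses
block 101 on 192 px canvases; the 51 px default suits finer structure).

## Design choices made where the design was open

- **Blend window**: linear tent rather than cosine — partition of unity
  is exact at 50% overlap, and the overlap-midpoint weights average 0.5.
- **Adversarial default**: the printed log (cross-entropy) form with a
  non-saturating generator update; the least-squares variant common in
  reference implementations is a config switch. Both train stably on the
  fixtures; neither is asserted as canonical.
- **Upsampling**: nearest-neighbor + conv instead of transposed conv, to
  avoid checkerboard artifacts that blending would otherwise have to hide.
- **Tiny-preset stem kernels 3×3** (full preset keeps 7×7): at 64 px
  tiles the receptive-field loss is negligible and full-resolution 7×7
  convolutions dominate CPU cost.
- **Seeding**: every stage draws from one seeded generator per call;
  dataset builders spawn child seeds per pair; no global RNG state is
  touched. Identical config + seed reproduces files byte-for-byte.

## Known limitations

- The numpy engine is single-device and unsuitable for the full-scale
  architecture on large datasets; it exists to make the method fully
  testable, not fast.
- The toy extractor's FID/KID scale is incommensurable with
  Inception-based reports; only orderings transfer.
- Registration assumes a projective model; real tissue deformation during
  staining has elastic components this cannot capture.
- Whole-slide inference holds the blended accumulator in memory; pyramid
  or tiled-TIFF output for gigapixel slides is out of scope.
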