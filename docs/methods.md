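# Methods

## The segmentation model

MC-UNet is a U-shaped encoder/decoder for per-pixel retinal vessel
classification. The network has four resolution levels and three skip
connections (one fewer level than the classic five-level U-Net). Each
level is a double unit of Conv3×3 → DropBlock → BatchNorm → ReLU;
encoder levels end in 2×2 max pooling, decoder levels start from a 2×2
transposed convolution and concatenate the same-resolution encoder
feature. Channel widths double per level from `base_channels`
(default 16 → 16, 32, 64, 128). A final 1×1 convolution plus sigmoid
yields a vessel probability per pixel.

The bottleneck combines three mechanisms that target the loss of thin,
low-contrast microvessels in plain encoder/decoder networks:

- **Spatial attention (SA).** Channel-wise max and mean pools of the
  bottleneck feature `F` are stacked into a 2-channel map, a 7×7
  convolution (3-pixel zero padding, with bias) and a sigmoid produce a
  single-channel gate `att ∈ (0,1)`, and `SA = F ⊙ att`. Only the
  spatial gate is used; no channel attention.
- **Dense atrous convolution (DAC).** Atrous (dilated) convolution
  `y[i] = Σ_k x[i + r·k] w[k]` enlarges the receptive field without
  downsampling; a 3×3 kernel at rate r covers (2r+1)×(2r+1). From the
  rate list (1, 3, 5) four parallel cascades are built — (1), (3),
  (1,3), (1,3,5) — with ReLU after each convolution and a 1×1
  projection closing every cascade except the plain rate-1 branch. Each
  branch output is added residually onto the input, so zero-initialised
  branches reduce to identity.
- **Multikernel pooling (MKP).** Max pooling with windows 2, 3, 5, 6
  (stride = window, ceil mode so non-divisible extents are padded),
  each pooled map squeezed to one channel by a 1×1 convolution and
  upsampled back (nearest-neighbour by default, so the appended maps
  are piecewise constant over pooling cells; bilinear selectable).
  The four context channels are concatenated onto the input
  (C → C + 4).

The fusion concatenates `SA` with `MKP(DAC(F))` (128 + 132 = 260
channels at the default width) and reduces back to the decoder width
with a 3×3 convolution. The concatenation follows the architecture's
verbal description; an additive fusion mode exists behind
`fusion_mode="sum"` for ablation, in which the context branch is first
reduced to the decoder width. Both SA and the DAC→MKP branch consume
the raw bottleneck feature (parallel form). With `use_dac=False,
use_mkp=False` the bottleneck degenerates to the attention backbone;
these two flags generate the four-variant ablation suite
(backbone, +DAC, +MKP, full).

## Parameter budget

`count_parameters` sums every learnable scalar (convolution weights and
biases, batch-norm scale/shift; running statistics are not learnable).
At the default widths the variants enumerate to 0.631 / 0.784 / 1.861 /
1.866 M (backbone / +MKP / +DAC / full), strictly ordered the same way
as the published ablation (0.54 < 0.69 < 2.36 < 2.37 M) and all far
below the 7.76 M of the original five-level U-Net. The absolute
published values cannot be pinned because the reference widths are not
published; the ordering and the budget bound are the tested contracts,
and the per-module increments are verified against closed-form counts.

## Numerical core

No deep-learning framework is used: `mcunet.tensor` is a compact
reverse-mode autodiff engine on NumPy arrays implementing exactly the
operations the network needs (im2col dilated convolution, 2×2
transposed convolution, ceil-mode max pooling, nearest/bilinear
upsampling, batch norm, channel max/mean, concatenation, sigmoid/ReLU,
and a log-sum-exp-stabilised binary cross-entropy on logits). All
backward passes are hand-derived and verified against central finite
differences; the convolution forward is additionally cross-checked
against `scipy.signal.correlate2d`. Arrays are float64 throughout —
slower than float32 but it keeps oracle tolerances tight.

## Regularisation

DropBlock zeroes contiguous `block_size × block_size` squares during
training: Bernoulli seed points drawn at rate
γ = (1−keep_prob)/bs² · HW/((H−bs+1)(W−bs+1)) on the valid-centre
region are dilated to squares, and survivors are rescaled by
count/kept per feature map so the expected activation mass is
preserved (verified by Monte-Carlo within three standard errors).
Defaults `block_size=7`, `keep_prob=0.82` follow the convention of the
spatial-attention U-Net family; the hyperparameters are unpublished for
the reference architecture. DropBlock sits symmetrically in encoder
and decoder blocks and is exactly identity at inference or at
`keep_prob=1`.

## Metrics

Evaluation is FOV-restricted by default (standard for these
benchmarks; `use_fov=False` evaluates all pixels). From pooled
confusion counts over all FOV pixels of all images:
ACC = (TP+TN)/(TN+FP+TP+FN), SE = TP/(TP+FN), SP = TN/(TN+FP),
F1 = 2TP/(2TP+FP+FN). Probabilities are binarised at 0.5
(config-exposed). Per-image averaging is available but pooled is the
default; the two conventions genuinely differ and the reference
reports do not disambiguate which was used. AUC comes from a full
threshold sweep (no intermediate-point dropping) with trapezoid
integration, and is tested to equal the exhaustive pairwise statistic
P(s⁺ > s⁻) + ½P(tie) to 1e-12. Degenerate denominators (an image with
no vessels) return 0.0 with a `RuntimeWarning` instead of raising;
single-class AUC raises, as no convention is defensible there.

## Synthetic data generator

`mcunet.synthetic` emulates the structure of the public fundus
benchmarks so every pipeline stage is testable without downloads: a
warm-toned bright disc (radial brightness falloff 0.72 → 0.47 of full
scale) on black background, vessels as smoothly turning random walks
seeded on the FOV boundary heading inward, branching with probability
0.035 per step at reduced calibre (parent ×0.88, child ×0.72, plus a
continuous ×0.995 per-step taper) from 4.5 px roots down to 1 px
microvessels, darkened by `contrast` (factor 1 − 0.45·contrast, so at
contrast 1 the noiseless classes separate strictly), plus Gaussian
noise (sd 8 of 255 by default). Defaults give an FOV vessel fraction
of 0.06–0.15 over 100 seeds (mean ≈ 0.12), matching the sparsity
regime of real vessel ground truth; the test bound [0.03, 0.20] was
frozen from that calibration run. All randomness flows through
`numpy.random.SeedSequence`, and rasters are integer, so outputs are
bit-identical across platforms for a fixed seed.

What the generator does **not** emulate: optic disc and fovea, lesions
and exudates, illumination artefacts, inter-image colour variation,
and the tortuosity statistics of real vasculature. Passing tests
therefore demonstrate that the architecture, optimisation and metrics
work as specified — not that the published benchmark numbers on DRIVE,
STARE or CHASE_DB1 are reproduced; those require the real datasets and
GPU-scale training and are out of scope.

## Training

Optimiser settings are unpublished for the reference architecture, so
the package defaults to the field's standard recipe: Adam (β 0.9/0.999)
at learning rate 1e-3, per-pixel binary cross-entropy on logits over
full padded images (soft Dice and BCE+Dice selectable), batch size 2,
optional early stopping on a training-loss plateau (`patience`). The
best-loss state is restored at the end of training. Images are scaled
to [0, 1] and padded reflectively to extents divisible by 2^(depth−1)
(a 565×584 DRIVE frame becomes 568×584); predictions are cropped back.
No colour preprocessing (CLAHE, green-channel extraction) is applied by
default.

Problem sizes in the test and acceptance runs are chosen for a
single-CPU NumPy engine: 64×64 synthetic images, `base_channels` 4–8,
and a 200-step overfit run on four images, which reaches train
Dice ≥ 0.99 and is the capacity check for the assembled architecture
(DropBlock disabled there — the check targets learning capacity, not
regularisation). A 60-epoch train/test run on eight synthetic images
lands around 96% AUC on the held-out half.

## Design choices on genuinely open points

- DAC branch wiring is config-driven (`DACBlock(branches=...)`); the
  default four-cascade topology follows the published dense-atrous
  design restricted to rates (1, 3, 5). ReLU but no BN inside
  branches.
- The residual Σ in the DAC is summation onto the input; the fusion Σ
  is concatenation — the prose description wins over the symbolic "+"
  there, with `fusion_mode="sum"` kept for ablation.
- Decoder upsampling is a 2×2 transposed convolution;
  nearest-neighbour + 1×1 convolution selectable.
- STARE and CHASE_DB1 ship no FOV masks or official split: FOVs are
  derived by luminance thresholding (cutoff 30/255, morphologically
  closed), and the first half of the sorted ids is the train split,
  both overridable.
- Bottleneck spatial extents must exceed the largest dilation rate and
  pooling kernel; at depth 4 this means inputs of at least 48×48
  (bottleneck ≥ 6×6). Inputs are validated and the error message
  points at `predict_image`, which handles arbitrary extents by
  padding.

## Known limitations

- Pure-NumPy training is orders of magnitude slower than a GPU
  framework; the package is sized for method verification and small
  studies, not benchmark-scale training.
- Batch norm with very small batches (1–4) uses noisy batch statistics;
  running statistics converge only over many steps.
- The ceil-mode pooling grid of MKP is not flip-symmetric on
  non-divisible extents, so exact flip-equivariance tests exclude MKP.
- Bit-exact reproducibility is guaranteed for the generator (integer
  rasters); trained parameters are reproducible run-to-run on the same
  BLAS, which is the determinism contract tested.
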