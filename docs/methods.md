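# Methods

## Problem and model

`hippseg` segments the hippocampus — a small bilobed gray-matter structure —
from 3D T1-weighted MR volumes into three classes: background (0), anterior
lobe / head (1) and posterior lobe / body+tail (2). The difficulties the
design targets are the tiny foreground fraction (a few percent of voxels),
the low tissue contrast at the lobe boundaries, and the smooth multiplicative
intensity inhomogeneity ("bias field") of MR acquisition.

The segmentation model is an adversarially trained generator with two
critics:

**Generator.** A 3D U-shaped encoder-decoder (the feature extraction module,
FEM) with four 2x max-pooling stages, so every input dimension must be
divisible by 2^4. A 48x64x48 patch passes through feature maps of
24x32x24, 12x16x12, 6x8x6 and 3x4x3. Each stage is two
(3x3x3 convolution → batch norm → ReLU) blocks; decoder stages upsample
(nearest-neighbour) and concatenate the matching encoder skip. Two
convolutional classification heads (FCM: a 3x3x3 then a 1x1x1 convolution
and a 3-class softmax) emit probability maps at full resolution (P_t4)
and at half resolution (P_t3, from the penultimate decoder level).

**Information-constraint unit (ICL).** At the deepest encoder level, a
convolutional gate (3x3x3 convolution → ReLU → sigmoid) produces a salience
map V_saf in (0,1); the features passed to the decoder are (1 − V_saf) ⊙ f.
The constraint loss CL is the closed-form Gaussian divergence of the
constrained features from a standard-normal prior, computed from per-channel
empirical moments: CL = mean_c (mu_c² + s_c² − 1 − ln s_c²)/2, clamped at 0
and with channel variances floored at 1e-8. This is a deterministic,
testable estimator; a variational sampling estimator would converge to the
same value in expectation. Note that the ReLU feeding the sigmoid floors the
gate at 0.5 wherever the pre-activation is negative; the gate therefore
operates in [0.5, 1), which only rescales the constrained features and does
not change the structure of the penalty.

**Attention blocks (MFCM).** At the last two decoder levels, a channel
self-attention block: the input is projected by a 1x1x1 convolution and
flattened to F′ ∈ R^{C×N} (N = D·H·W); the attention matrix is the
row-softmax of F′F′ᵀ (C×C, rows summing to 1); A·F′ is reshaped and
projected back by a second 1x1x1 convolution into M_feature. The output is
δ·M_feature + refine(input), with refine a 3x3x3 convolution and δ a
learnable scalar initialized at 0, so attention starts as an identity-like
residual and cannot destabilize early training.

**Discriminators.** D1 (full resolution) and D2 (half resolution) are five
stride-2 convolutions with kernels 7/5/3/3/3 and ReLU between layers; the
fifth layer maps to one channel so the critic is exactly five convolutions;
global average pooling and a sigmoid give a scalar probability that the
input map is a real (one-hot) label rather than a generated probability map.
The discriminators see probability/one-hot maps only, not the image. D2's
real branch uses the one-hot labels block-averaged to half resolution —
averaging indicator channels yields valid per-voxel class fractions without
interpolation artifacts.

## Losses

- Segmentation, per output scale: sigma1·BCE + sigma2·Dice with
  sigma1 = 0.6, sigma2 = 0.4, applied one-vs-rest to classes 1 and 2 and
  averaged. The BCE weights the positive class by beta_bce (default 0.7,
  protecting the minority foreground; configurable since no numeric value
  is prescribed for it). Probabilities are clipped at 1e-7 before logs;
  Dice is smoothed by 1e-5 in numerator and denominator.
- Adversarial: the standard minimax value log D(z) + log(1 − D(G(x))). The
  discriminators maximize it; the generator minimizes log(1 − D(G(x))). At
  the 0.5/0.5 equilibrium the value is 2·ln 0.5 ≈ −1.386.
- Information constraint: the CL term above.
- Total: 1.0·L_seg4 + 0.2·L_seg3 + 0.005·L_adv1 + 0.002·L_adv2 + 0.001·CL.
  These default weights sum to 1.208 rather than 1; they are used as
  configured, without renormalization (config validation logs the sum).

## Training

Alternating per batch: one update of each discriminator (SGD, momentum 0.9)
on a detached fake map and the real one-hot target, then one generator
update (Nadam). The learning rate follows base_lr·(1 − iter/max_iter)^power
per step with base_lr 2.5e-4, power 0.9, max_iter 500, clamped to zero
afterwards. Full-scale defaults: batch 16 with at least 1/3 of patches
guaranteed to contain foreground (enforced per batch as ceil(batch/3) via
rejection resampling), 150 epochs, base width 32, tenfold cross-validation.
Weight init is He-normal N(0, sqrt(2/fan_in)); batch-norm scale 1, shift 0.

Whole runs are pure functions of (config, dataset, seed). Checkpoints store
every parameter and buffer and round-trip bit-exactly.

### Desk-scale preset

`TrainConfig.desk()` is the CPU-scale configuration used in tests: width-4
generator, width-2 discriminators, 16x32x16 patches, batch 4, 50 steps per
epoch for 2 epochs, base learning rate 5e-3. The raised learning rate is
deliberate: with ~100 adaptive-optimizer steps at greatly reduced width and
batch size, the benchmark rate of 2.5e-4 cannot traverse a comparable
distance in parameter space; 5e-3 lets the small model reach clearly
above-baseline validation Dice within two epochs. Patches of 16x32x16 keep
the deepest feature level at 1x2x1 (the minimum for per-channel moment
estimates) and cover the two lobes along their long axis.

## Preprocessing

- Patches: half-open crop windows centred at a voxel (start = center −
  size//2); regions outside the source are zero-filled and flagged in a pad
  mask. Every dimension must divide by 16.
- Z-score normalization per patch; constant (all-padding) patches map to
  zeros rather than erroring, since they arise by construction.
- Augmentation (per patch, selected with probability 0.95 each epoch):
  independent mirror per axis (p = 0.5), one rotation about a random axis
  with angle uniform in [−15°, 15°] (trilinear for the image, nearest for
  the label so classes are preserved), and an additive intensity shift
  uniform in [−0.1σ/2, +0.1σ/2] with σ the patch standard deviation.
- Bias-field correction: N4 (SimpleITK, stock settings) with a tissue mask.
  Five masking strategies are provided — mean-binary, iterative mean-update,
  Sauvola and Niblack (local 16x16x16 windows), and Otsu (the default;
  maximizes between-class variance). A dependency-light alternative
  (`method="polyfit"`) fits a low-order polynomial to log intensities within
  the mask, centred to geometric mean 1. Both return the field itself so
  corrected × bias reconstructs the input exactly.

## Postprocessing and metrics

Per voxel: foreground iff P_ant + P_pos > 0.5, then the larger of the two
lobe probabilities (ties to anterior); else background. Connected-component
filtering pools classes 1 ∪ 2 (per-class filtering would wrongly split the
two adjacent lobes), labels under 26-connectivity, and removes components
smaller than 27 voxels — a full 3x3x3 cube is the smallest acceptable
component. The filter is idempotent and never adds foreground.

DSC, PPV and SEN are computed from binary confusion counts per class with a
smoothing constant 1e-5 added symmetrically, so a perfect match scores ≈ 1
and the both-empty case is defined (all three equal 1). DSC is the harmonic
mean of PPV and SEN up to smoothing.

## Synthetic subjects

The generator emulates the statistical structure the pipeline assumes, not
anatomy: per-axis extents uniform in W ∈ [31,43], H ∈ [40,59], D ∈ [24,47]
voxels at 1 mm isotropic spacing (the ranges of the MSD hippocampus
training scans); two touching ellipsoidal lobes along the H axis, labelled
1 (anterior) and 2 (posterior), disjoint, each 26-connected, and mutually
26-adjacent; class mean intensities 100/160/140 with ±8% per-subject
contrast jitter; additive Gaussian noise (sd 10) with an optional Rician
mode; and a multiplicative bias field exp(poly) of order ≤ 3 in normalized
coordinates with coefficients uniform in ±0.15, strictly positive by
construction. Under these defaults the foreground occupies ≈ 1.9–2.5% of
voxels, comfortably inside the small-structure regime (0.1%–10%) the
method targets. Everything is a pure function of (spec, seed), and subject
i of a dataset is reproducible from (seed, i) alone.

What the synthetic data does **not** model: real hippocampal shape
variability and atrophy, partial-volume effects, scanner-specific noise
correlation, and neighbouring gray-matter structures with confusable
intensity (the amygdala). Passing tests therefore demonstrate that the
pipeline's machinery is correct and that training converges on
well-separated structures — not that benchmark-level accuracy transfers to
clinical MR data.

## Numerical choices

- All network arithmetic is float64 on a small reverse-mode autodiff core
  written for this package (numpy only); gradient correctness is verified
  against central differences at 1e-6.
- Probability clipping 1e-7; Dice smoothing 1e-5; metric smoothing 1e-5;
  constraint-variance floor 1e-8; batch-norm eps 1e-5, momentum 0.1.
- Max-pooling is kernel-2/stride-2 (the architecture requires exact
  halving). Upsampling is nearest-neighbour.
- Eq-style decision ties (P_ant = P_pos) go to anterior; the sum boundary
  is strictly greater-than 0.5.
- Otsu/Sauvola/Niblack thresholds delegate to scikit-image; the iterative
  mean-update rule is implemented directly (t ← mean of class means until
  fixed); constant images yield an all-background mask with a warning.

## Known limitations

- Desk-scale training (minutes on one CPU) demonstrates convergence
  direction, not benchmark accuracy; reproducing published hippocampus
  scores requires the external MSD dataset and GPU-scale training, both out
  of scope here.
- N4 on tiny two-class synthetic volumes can absorb part of the tissue
  contrast into the estimated field; the correction contracts are therefore
  tested on fixtures where the assumption "one tissue class inside the
  mask" or "bias dominates within-class variation" actually holds.
- The discriminator judges whole maps with a single scalar; patch-level
  (PatchGAN-style) judgments are not implemented.
- No surface-distance metrics (HD95/ASSD); evaluation is overlap-based.
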