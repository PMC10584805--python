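# hippseg

Adversarial 3D segmentation of the anterior/posterior hippocampus in
T1-weighted MR volumes.

The hippocampus occupies only a few percent of a brain MR crop, its two
lobes (head, label 1; body+tail, label 2) touch along a low-contrast
boundary, and MR intensities carry smooth multiplicative inhomogeneity.
`hippseg` implements a full pipeline for this regime:

- **NIfTI I/O** with geometry preservation and strict label vocabulary
  checks ({0, 1, 2});
- **preprocessing** — foreground-guaranteed 3D patch sampling (≥ 1/3 of
  each batch contains foreground), z-score normalization, N4 bias-field
  correction guided by Otsu (or mean/iterative/Sauvola/Niblack) masking,
  and mirror/rotation/intensity augmentation;
- **the segmentation GAN** — a four-level 3D U-shaped generator with an
  information-constraint gate at the bottleneck and channel self-attention
  at the last two decoder levels, judged by two five-layer convolutional
  discriminators at full and half output resolution;
- **training** — alternating D/G optimization (SGD momentum 0.9 for the
  critics, Nadam for the generator) under a polynomial learning-rate decay
  `2.5e-4 · (1 − iter/500)^0.9`, with a k-fold cross-validation harness;
- **postprocessing and metrics** — the voxel rule *foreground iff
  P_ant + P_pos > 0.5* (then argmax over the two lobes), removal of
  connected components smaller than 27 voxels (26-connectivity, classes
  pooled), and DSC/PPV/SEN with smoothing 1e-5.

The objective is

```
L = λ1·L_seg4 + λ2·L_seg3 + γ1·L_adv1 + γ2·L_adv2 + β·CL
  (λ1=1, λ2=0.2, γ1=0.005, γ2=0.002, β=0.001)
```

with `L_seg = 0.6·BCE_β + 0.4·Dice` applied one-vs-rest to the two lobes
and `CL = mean_c (μ_c² + s_c² − 1 − ln s_c²)/2`, the Gaussian divergence of
the gated bottleneck features from N(0, 1).

Networks run on a small numpy reverse-mode autodiff core included in the
package (`hippseg.nn`), verified against central differences; everything is
seeded and bit-reproducible.

A built-in synthetic-subject generator stands in for clinical data in all
tests: volumes with per-axis extents W∈[31,43], H∈[40,59], D∈[24,47]
containing two touching ellipsoidal lobes, class-dependent intensities,
noise, and an exponential-polynomial bias field.

## Worked example

```python
import numpy as np
from hippseg import (SyntheticSpec, generate_subject, threshold_mask,
                     correct_bias_field, cca_filter, evaluate_pair)
from hippseg.io_volumes import LabelVolume

spec = SyntheticSpec(seed=0)
volume, label = generate_subject(spec, np.random.default_rng(0))
print(f"subject extents: {volume.shape}, foreground fraction: "
      f"{label.foreground_mask().mean():.2%}")

mask = threshold_mask(volume, "otsu")
corrected, bias = correct_bias_field(volume, mask)
print(f"estimated bias field range within mask: "
      f"[{bias.values[mask].min():.3f}, {bias.values[mask].max():.3f}]")

noisy = label.values.copy()
noisy[2, 2, 2] = 1            # a 1-voxel false-positive island
cleaned = cca_filter(LabelVolume(noisy))
result = evaluate_pair(cleaned, label)
for cls, name in ((1, "anterior"), (2, "posterior")):
    m = result.per_class[cls]
    print(f"{name}: DSC={m['dsc']:.4f} PPV={m['ppv']:.4f} SEN={m['sen']:.4f}")
```

prints

```
subject extents: (42, 52, 36), foreground fraction: 2.31%
estimated bias field range within mask: [0.863, 1.545]
anterior: DSC=1.0000 PPV=1.0000 SEN=1.0000
posterior: DSC=1.0000 PPV=1.0000 SEN=1.0000
```

The subject's two lobes fill 2.31% of the volume; N4 recovers a smooth
field close to 1; the 27-voxel component filter deletes the injected
single-voxel island, so the cleaned prediction matches the reference
exactly and all metrics are 1.

Training end to end (CPU-scale preset: width-4 generator, 16×32×16
patches, 2 epochs of 50 steps):

```python
from hippseg import TrainConfig, train_alternating, evaluate_model
from hippseg.synthetic import generate_dataset

train_set = generate_dataset(spec, 10, seed=42)
val_set = generate_dataset(spec, 3, seed=43)
bundle, history = train_alternating(train_set, TrainConfig.desk(seed=1),
                                    val_dataset=val_set)
print(evaluate_model(bundle.generator, val_set))
```

On the synthetic blobs this raises mean validation DSC from ≈ 0.02
(untrained, near-uniform probabilities) to ≈ 0.12–0.17 within the two
epochs, with every loss component finite and the run exactly reproducible
from its seed.

## Command line

```
hippseg synth   --n 20 --seed 0 --out data/          # synthetic MSD layout
hippseg train   --config cfg.yaml --data data/ --out run/ [--folds 10]
hippseg predict --checkpoint run/checkpoint.npz --in data/imagesTr --out pred/
hippseg evaluate --pred pred/ --gt data/labelsTr --report report.csv
```

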