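# adreseg

Volumetric segmentation of adrenal tumors in contrast-enhanced CT, built
around an encoder–decoder network with depthwise-separable 3D
convolutions (DSConv) and a transformer bottleneck, trained with a soft
Dice loss. Adrenal metastases are small — on average the tumor occupies
about 0.267 % of a scan — irregularly located, often bilateral, and have
blurred margins, which makes both the segmentation task and its
evaluation strongly imbalance-dominated. The package is aimed at
medical-image-analysis researchers who want a tested, CPU-runnable
reference implementation of this architecture family together with the
full experimental scaffolding: synthetic CT phantoms with known ground
truth, the preprocessing chain, slab-wise training and whole-volume
inference, the five standard evaluation metrics, and the
method-comparison statistics.

## The model

The input volume (window level/width 40/300 HU, in-plane grid halved,
z resampled to 1 mm, min–max normalized to [0, 1]) is encoded by a stem
plus four stages of DSConv units; each stage halves every spatial
dimension and doubles the channel width, ending at a bottleneck
X′ ∈ R^(C′ × W/16 × H/16 × D/16) with C′ = 256. The bottleneck is
reshaped channel-wise into a sequence of C′ tokens, each token the
flattened spatial map of one channel (dimension N = W/16 · H/16 · D/16),
a learnable positional embedding P ∈ R^(256 × N) is added, and a stack of
pre-norm transformer layers applies 8-head scaled-dot-product attention

    head_h = softmax(Q W_h^Q (K W_h^K)ᵀ / √d_k) · V W_h^V,
    MHA(Q,K,V) = concat(head_1 … head_8) · W^O,   d_k = d_v = N/8,

followed by a feed-forward network. The decoder maps tokens back onto
the bottleneck grid and upsamples four times with transposed
convolutions, concatenating the saved encoder feature map at each
resolution (skip connections), and ends in a single-channel sigmoid
head. Training uses Adam (weight decay 1e-5, batch size 2, seed 1000),
a learning rate decaying from 2e-4 at epoch 0 to 4e-7 at epoch 999, an
80/20 case-level split, random 32-slice slabs as inputs, and the soft
Dice loss 1 − (2Σpg + ε)/(Σp + Σg + ε).

Evaluation: Dice score (DSC), intersection over union (IOU), Hausdorff
distance, average surface distance (ASD, directed prediction→truth) and
mean absolute voxel error (MAE), with surfaces taken as 6-connectivity
boundary voxels and distances in millimetres. Methods are compared with
Levene's test for variance homogeneity followed by Student's t
(pooled variance, or Welch's correction when Levene rejects).

Because no public dataset exists for this task, the `phantom` module
generates synthetic abdominal-CT-like cohorts — soft-tissue intensity
ranges, one or two ellipsoidal tumors per case (expected bilateral share
49/182), tumor long axis ≥ 10 mm, expected tumor volume fraction
0.267 %, blurred contours, heterogeneous interiors, variable slice
counts — so every pipeline stage is testable end to end.

The network and optimizer run on a compact NumPy reverse-mode autodiff
engine (`adreseg.autodiff`) with numba-accelerated depthwise
convolutions; no GPU or deep-learning framework is required.

## Worked example

```python
from adreseg import TumorSegmenter, make_cohort
from adreseg.experiments import preprocess_cases
from adreseg.trainer import split_cases

cases = preprocess_cases(make_cohort(25, seed=1000, grid_xy=128,
                                     spacing=(1.25, 1.25, 1.0),
                                     slice_range=(32, 64)))
train_set, test_set = split_cases(cases, 0.8, seed=1000)

est = TumorSegmenter(stem_channels=8, slab_depth=16, epochs=45,
                     lr_initial=1e-2, lr_final=2e-3, warmup_epochs=4,
                     fg_slab_bias=0.5, adam_beta2=0.99, seed=1000)
est.fit(train_set)
print(f"mean held-out Dice: {est.score(test_set):.3f}")
```

This trains the reduced (stem-8) model on 20 synthetic cases for 450
optimizer steps (a few minutes on one CPU core) and prints

```
mean held-out Dice: 0.854
```

— the mean Dice overlap between predicted and ground-truth tumor masks
on the 5 held-out phantoms, i.e. the model recovers ~85 % of the
tumor/prediction mass overlap on unseen cases at this reduced scale.
The same configuration run through
`adreseg.experiments.generalization_smoke` (which stitches slabs with
an 8-slice overlap and computes all five metrics) reports a mean test
DSC of 0.868, per-case Hausdorff distances of 2.5–5 mm and directed
average surface distances below 1 mm.

The same pipeline is scriptable from the shell:

```bash
adreseg phantom --n 25 --seed 1000 --out raw/
adreseg preprocess --in raw/ --out prep/
adreseg train --data prep/ --config train.yaml --out run/
adreseg predict --model run/checkpoint.npz --in prep/ --out pred/
adreseg evaluate --pred pred/ --truth prep/ --out metrics.csv
adreseg compare --metrics-a metrics.csv --metrics-b other.csv --out cmp.json
adreseg ablate --data prep/ --config train.yaml --out ablation/
```

Every command writes a `manifest.json` (package version, seed, resolved
configuration hash, input checksums) next to its outputs.

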