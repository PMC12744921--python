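# slabseg

Hybrid 2D/3D convolutional segmentation of focal liver lesions from
stacks of adjacent CT slices.

## The problem

On portal-venous contrast CT the liver parenchyma enhances strongly and
most focal lesions appear hypodense — but vessels and dilated bile ducts
can show lesion-like intensity on any single slice, and lesions vary
widely in size, shape and number.  Segmenting slice by slice with a 2D
network therefore produces volumetrically inconsistent masks and vessel
false positives; full 3D networks capture the context but are expensive
and usually trained on small crops; conventional 2.5D networks (adjacent
slices stacked as input channels) fuse all slices in their very first
convolution, discarding slice identity.

`slabseg` implements a middle path: a U-Net whose encoder embeds a small
number of 3D convolutions into a 2D residual trunk.  The network takes
k = 7 adjacent slices as a depth axis and predicts a mask for the central
slice.  Each encoder stage applies one depth-reducing `d x 3 x 3` 3D
convolution in its first block (depth trajectory 7 → 6 → 5 → 4 → 2 under
`d = [2, 2, 2, 3]`), fuses it with a global pointwise path replicated
along depth, folds depth into channels (`C' = C x D`), and continues with
2D inverted-bottleneck residual blocks; the stage output concatenates the
last block with the first block's fused map.  Training minimises

    L = L_Tversky(alpha = 0.3, beta = 0.7) + 0.6 * L_BCE

with Adam (initial rate 2e-4) under cosine annealing with warm restarts
(period 300 iterations, floor 1e-6).  Evaluation reports per-case
sensitivity, specificity, Dice, volumetric overlap error and relative
volume difference with bootstrap 95% confidence intervals.

The package also provides the conventional 2.5D baseline (ResNet-18/50/101
encoder with 7-channel input and a U-Net decoder), a synthetic liver-CT
phantom generator so the full pipeline runs without patient data, and a
parameter audit.  All computation runs on a self-contained numpy
autodiff core — no GPU or deep-learning framework required.

## Worked example

```python
from slabseg import (PhantomSpec, SegmentationModel, TrainConfig,
                     generate_cohort, quarter_width_config)

spec = PhantomSpec(grid_shape=(12, 64, 64))          # desk-scale phantoms
cohort = generate_cohort(6, spec, seed=0)
model = SegmentationModel(cohort[:4], quarter_width_config(),
                          TrainConfig(iterations=150, batch_size=4, seed=0))
res = model.fit()
print(res.summary())
frame, summary = res.evaluate(cohort[4:], seed=0)
print(summary.to_frame().to_string(index=False))
```

prints

```
Mixed 2D/3D U-Net fit
==========================================
parameters                 1,865,909
input slices (k)                   7
depth trajectory       7->6->5->4->2
iterations                       150
loss, first 10 iters          1.2188
loss, last 10 iters           0.7669
norm mean / sd         0.6439/0.0506
metric      mean  ci95_lower  ci95_upper
   sen 99.723948   99.633252   99.814643
   spe 85.873404   84.485253   87.261555
  dice 29.026295   20.924262   37.128329
   voe 82.759675   77.203937   88.315412
   rvd  5.449983    3.376738    7.523227
```

After 150 iterations the quarter-width model already finds essentially
every lesion voxel (sensitivity 99.7%) but still over-segments heavily
(RVD ≈ 5.4, i.e. the predicted volume is about six times the reference),
so Dice is low — the recall-weighted Tversky loss drives recall first and
precision tightens with further training.  The loss falling from 1.22 to
0.77 shows optimisation under way; the summary also records the cohort
intensity statistics used at inference.

The same pipeline is available from the shell:

```sh
slabseg phantom --n-cases 4 --seed 1 --out data/
slabseg train --data data/ --out run/ --seed 0
slabseg predict --checkpoint run/checkpoint.pkl --in data/phantom-1-000_ct.nii.gz --out pred.nii.gz
slabseg evaluate --checkpoint run/checkpoint.pkl --data data/ --report report/
slabseg audit
```

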