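# camseg

Channel-attention encoder-decoder segmentation of lung tumors in 3D CT.

Lung tumors occupy a fraction of a percent of a thoracic CT scan, and the
boundary between tumor and surrounding lung is where segmentation networks
fail. `camseg` implements **SegChaNet**, an encoder-decoder network whose
skip connections pass through a **channel attention module (CAM)**: each
low-level encoder map X_L is re-weighted, channel by channel, by a globally
pooled descriptor of the high-level decoder map X_H before the two are
fused —

```
X_L′  = conv3(X_L)                      # align channels, 3×3×3
g     = GAP(X_H)                        # one scalar per channel
X_gL  = conv1(X_L′) ⊙ g                 # channel k scaled by g[k]
X_cam = X_gL + up(X_H)                  # + trilinearly upsampled X_H
```

so high-level semantics steer which fine-grained channels survive into the
decoder. The package is a complete, self-contained pipeline for people who
want to study or extend this family of models:

- CT preprocessing: HU truncation to [−1000, 400], per-scan z-normalization,
  cubic resampling (default 128³), seeded flip/inversion/±10° augmentation;
- three architectures behind one interface: U-Net, V-Net and SegChaNet
  (with CAM on/off, dilated bottleneck, optional deep supervision);
- compound losses 2−(IOU+DSC) and dice+BCE;
- the training protocol: Adam, validation-BCE plateau schedule (×0.1 after
  15 stagnant epochs), the published 9-point hyperparameter grid, k-fold
  majority-vote ensembling, grad-CAM saliency;
- volumetric metrics: DSC, IOU/JI, sensitivity/specificity/precision,
  Hausdorff distance and normalized surface distance (NSD) at 4 mm;
- a seeded thorax-phantom simulator (HU-valued lungs, airways and 5–32 mm
  nodules with ground-truth masks) so everything runs without patient data.

The networks run on a compact numpy reverse-mode autodiff engine built into
the package — no GPU or deep-learning framework required; every operator is
finite-difference-checked in the test suite.

## Worked example

Train a reduced SegChaNet on synthetic phantoms and evaluate held-out
cases (≈3 minutes on one CPU core):

```python
import numpy as np
from camseg import (SegmentationModel, NetworkConfig, TrainConfig,
                    PhantomSpec, PreprocessConfig)
from camseg.phantoms import generate_phantom
from camseg.preprocess import preprocess_case

spec = PhantomSpec(shape=(32, 32, 32), spacing=(3.0, 3.0, 3.0),
                   nodule_diameter_mm=(9.0, 21.0))
prep = PreprocessConfig(target_shape=(32, 32, 32))

def cases(n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for s in rng.integers(0, 2**31 - 1, size=n):
        c = generate_phantom(spec, int(s))
        vol, mask = preprocess_case(c.volume, c.mask, prep)
        out.append((vol.data.astype(np.float32), mask.data))
    return out

model = SegmentationModel(
    train_cases=cases(12, seed=0),
    network=NetworkConfig(depth=3, base_channels=8, use_cam=True,
                          dilation_schedule=(1, 2)),
    train=TrainConfig(epochs=30, minibatch=4, initial_lr=1e-3, seed=0),
)
results = model.fit()
print(results.summary())
print(results.evaluate(cases(2, seed=99))[["dsc", "iou", "nsd"]].round(3))
```

Output:

```
Segmentation model fit
======================================================
architecture:     SegChaNet
depth / base ch.: 3 / 8   channel attention: on
parameters:       154,337
loss:             eq6   optimizer: Adam(lr=0.001)
epochs run:       30
final train loss: 0.2752
final lr:         0.001
======================================================
     dsc    iou    nsd
0  0.947  0.900  1.000
1  0.835  0.717  0.877
```

`dsc`/`iou` are voxel-overlap scores of the thresholded prediction against
ground truth (1 = perfect); `nsd` is the fraction of the two mask surfaces
within 4 mm of each other. The model recovers held-out nodules with DSC
0.84–0.95 after 30 epochs on 12 phantoms — a machinery check at toy scale,
not a clinical benchmark (see `docs/methods.md`).

The same workflow is scriptable from a shell:

```bash
camseg simulate --n 10 --seed 3 --out runs/demo
camseg train runs/demo runs/exp1 --epochs 20
camseg predict runs/exp1/checkpoint.npz runs/demo/case_009.nii.gz pred.nii.gz
camseg evaluate pred.nii.gz runs/demo/case_009_mask.nii.gz
```

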