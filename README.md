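# gpseg

Patient-specific 3D segmentation of the globus pallidus externa and interna
(GPe/GPi) — the nested basal-ganglia nuclei targeted by deep brain
stimulation for Parkinson's disease and dystonia — from isotropically
resampled T2-weighted MRI volumes.

Accurate DBS electrode placement needs the GPi and its boundary with the
GPe (the thin internal medullary lamina) delineated per patient, not copied
from an atlas.  `gpseg` provides the full pipeline for a deep-learning
approach to this problem:

* an **attention-gated 3D U-net with deformable convolutions**: four
  encoder/decoder stages, large dilated kernels at full resolution
  (kernel 11 dilation 3, kernel 9 dilation 2), deformable-convolution
  blocks in the deep stages, attention gates on decoder levels 2–4, and a
  kernel-1 classifier over {background, GPe, GPi};
* the **composite training objective**

  `L = mean_c (1 − TI_c) + 0.01 · overlap + w(epoch) · HD-surrogate`

  where `TI_c = tp / (tp + α_c·fp + β_c·fn)` is the soft Tversky index with
  (α, β) = (0.7, 0.3) for background and (0.4, 0.6) for GPe and GPi, the
  overlap term is the soft Dice between each predicted class and every
  other class's truth, and the Hausdorff surrogate weights squared
  residuals by Euclidean distance transforms, with
  `w(epoch) = 10⁻⁵ · 5^⌊epoch/50⌋`;
* training with SGD (lr 10⁻⁴, momentum 0.9, batch 1) and sagittal-mirror
  augmentation; inference with connected-component cleanup (keep the two
  largest components per structure);
* every evaluation metric of the trade: Dice, centre-of-mass distance (mm),
  mean surface distance (mm), Hausdorff distance (mm), volume (cm³),
  precision/recall, plus ANOVA + Tukey HSD significance matrices for
  comparing methods;
* a **synthetic phantom generator** producing bilateral nested GPe/GPi
  anatomy (volumes drawn from the reported manual distributions,
  1.25 ± 0.19 and 0.63 ± 0.12 cm³) with 7 T-like T2 contrast, noise, and
  optional motion-blur and vessel corruptions — so the whole method is
  trainable and verifiable without patient data.

The network and its gradients run on a small numpy autodiff core included
in the package (FFT-accelerated convolutions, trilinear deformable
sampling); no deep-learning framework is required.

## Worked example

`examples/03_train_and_segment.py` trains a small configuration (channel
width 4, 8 epochs, four 32³ phantoms at 1 mm) and segments a held-out
phantom:

```
 epoch  total  tversky  overlap  hausdorff
     0 0.7131   0.7001   1.2824    16.9855
     2 0.5878   0.5777   1.0000     6.6451
     4 0.5412   0.5322   0.8945     4.5438
     6 0.5181   0.5096   0.8424     4.0841

removed 31 island component(s)
GPe  left: dice 0.397, volume 4.79 vs 1.22 cm^3
GPe right: dice 0.395, volume 4.74 vs 1.20 cm^3
GPi  left: dice 0.751, volume 0.53 vs 0.73 cm^3
GPi right: dice 0.782, volume 0.59 vs 0.39 cm^3
```

All three loss terms fall as training proceeds.  After only eight epochs
the compact GPi is already localized (Dice ≈ 0.77); the thin GPe shell
converges much more slowly — it still over-covers background (4.7 vs
1.2 cm³), which is exactly the behaviour the island-removal and longer
schedules address.  The other examples generate phantom cohorts, evaluate
the loss terms and schedule, and build a Tukey significance matrix between
two synthetic "methods".

A thin CLI wraps the same pipeline for shell use:

```bash
gpseg phantom -n 8 --out-dir data --seed 1
gpseg train --data-manifest data/manifest.tsv --out-checkpoint model.npz --epochs 30
gpseg segment --checkpoint model.npz --image data/case_0000_img.nii.gz --out pred.nii.gz
gpseg evaluate --pred pred.nii.gz --truth data/case_0000_lab.nii.gz --out-report report.tsv
```

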