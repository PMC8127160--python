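"""Surface-distance metrics and the ANOVA/Tukey method-comparison matrix.

Builds two synthetic 'methods' — a faithful segmenter (small random erosions)
and a biased one (systematic dilation) — evaluates both against phantom truth,
and tests whether their Dice distributions differ significantly.
"""

import numpy as np
from scipy import ndimage

from gpseg import (PhantomSpec, sample_phantom_retry, evaluate_case,
                   significance_matrix)
from gpseg.volume_io import LabelVolume

spec = PhantomSpec(grid_shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0))
rng = np.random.default_rng(0)

faithful, biased = [], []
for seed in range(8):
    _, lab, _, _ = sample_phantom_retry(spec, 500 + seed)

    eroded = lab.data.copy()
    for cls in (1, 2):
        keep = ndimage.binary_erosion(lab.data == cls) | \
            ((lab.data == cls) & (rng.random(lab.data.shape) > 0.3))
        eroded[(lab.data == cls) & ~keep] = 0
    dilated = lab.data.copy()
    for cls in (2, 1):
        grown = ndimage.binary_dilation(lab.data == cls, iterations=2)
        dilated[grown & (dilated == 0)] = cls

    for variant, store in ((eroded, faithful), (dilated, biased)):
        report = evaluate_case(LabelVolume(variant, lab.spacing), lab)
        for e in report.entries:
            store.append(e.dice)

print(f"faithful method: dice {np.mean(faithful):.3f} +/- {np.std(faithful):.3f}")
print(f"biased method:   dice {np.mean(biased):.3f} +/- {np.std(biased):.3f}")

matrix = significance_matrix({"faithful": faithful, "biased": biased})
print(f"ANOVA F = {matrix.anova_f:.1f}, p = {matrix.anova_p:.2e}")
print(f"Tukey HSD category: {matrix.category(0, 1)}")
print("\n'p<0.001' means the two methods' Dice distributions are clearly")
print("distinct, mirroring how segmentation methods are compared in cohorts.")
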