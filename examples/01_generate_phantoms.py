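"""Generate a small synthetic phantom cohort and inspect its ground truth.

Each phantom is a bilateral pair of nested superellipsoids — an outer GPe
shell around an inner GPi, separated by a 1 mm lamina gap — with volumes drawn
from the reported manual distributions (GPe 1.25 +/- 0.19 cm^3, GPi
0.63 +/- 0.12 cm^3).
"""

import tempfile
from pathlib import Path

from gpseg import PhantomSpec, generate_dataset

out_dir = Path(tempfile.mkdtemp(prefix="gpseg_phantoms_"))
spec = PhantomSpec(grid_shape=(48, 48, 48), spacing=(0.78, 0.78, 0.78))
manifest = generate_dataset(spec, n=4, out_dir=out_dir, seed=42)

print(f"wrote {len(manifest)} image/label pairs to {out_dir}")
cols = ["case_id", "left_GPe_volume_cm3", "left_GPi_volume_cm3",
        "right_GPe_volume_cm3", "right_GPi_volume_cm3"]
print(manifest[cols].round(3).to_string(index=False))
print("\nVolumes are per-side ground truth in cm^3; they scatter around the")
print("population means 1.25 (GPe) and 0.63 (GPi) with SDs 0.19 and 0.12.")
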