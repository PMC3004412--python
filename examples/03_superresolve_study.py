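"""Reference-guided superresolution of a simulated anisotropic acquisition.

Simulates a 64^3 paired-contrast study where modality B was acquired with
2-mm slices, reconstructs it to 1 mm using the modality-A HR volume as
guidance, and compares against interpolation baselines. The reconstruction
must also remain exactly consistent with the LR data under the acquisition
model (its block means reproduce the LR input).
"""

import numpy as np

from mrsr import (
    DegradationSpec,
    PhantomSpec,
    RicianNoiseSpec,
    boxcar_downsample,
    simulate_study,
)
from mrsr.experiments import run_study

bundle = simulate_study(
    PhantomSpec(shape=(64, 64, 64), seed=1234),
    DegradationSpec(factors=(1, 1, 2)),
    RicianNoiseSpec(sigma=0.0, seed=0),
)
print(f"truth {bundle.hr_truth.shape}, LR input {bundle.lr_input.shape}, "
      f"reference {bundle.hr_reference.shape}")

result = run_study(bundle)
state = result.state
print(f"converged after {state.iteration} iterations "
      f"(final MAD {state.mad_history[-1]:.4f} < tol {state.tol_used})")
for method in ("nearest", "bspline", "proposed"):
    print(f"PSNR {method:8s}: {result.psnr_db[method]:6.2f} dB")

resid = np.abs(boxcar_downsample(result.x_hat, bundle.spec).data
               - bundle.lr_input.data).max()
print(f"subsampling-consistency residual ||DHx - y||_inf = {resid:.3g}")
print("higher PSNR = closer to the ground truth; the residual being at float "
      "precision means the reconstruction is physically consistent with the "
      "acquired LR data.")
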