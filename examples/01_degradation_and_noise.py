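"""The MR acquisition model: y = DHx + n.

Builds a tiny HR volume, degrades it with the boxcar block-averaging model,
and corrupts it with Rician noise, checking the noise statistics against
their closed forms.
"""

import numpy as np

from mrsr import (
    DegradationSpec,
    RicianNoiseSpec,
    Volume3D,
    add_rician_noise,
    block_replicate_upsample,
    boxcar_downsample,
)

# An HR volume whose intensities are just the raster index, 1 mm isotropic.
hr = Volume3D(np.arange(4 * 4 * 6, dtype=float).reshape(4, 4, 6), spacing=(1, 1, 1))

# Acquire it with 3 mm slices: every LR voxel is the mean of a 1x1x3 HR block.
spec = DegradationSpec(factors=(1, 1, 3))
lr = boxcar_downsample(hr, spec)
print(f"HR {hr.shape} @ {hr.spacing} mm  ->  LR {lr.shape} @ {lr.spacing} mm")
print("first LR column:", lr.data[0, 0], "= means of", hr.data[0, 0].reshape(2, 3))

# Block replication (nearest-neighbour upsampling) inverts exactly under DH:
rt = boxcar_downsample(block_replicate_upsample(lr, spec), spec)
print("round-trip max |dev|:", np.abs(rt.data - lr.data).max())

# Rician noise: Gaussian noise on both complex channels, then the modulus.
# At zero signal the mean is sigma*sqrt(pi/2); at high SNR E[M^2] = A^2 + 2 sigma^2.
zero = Volume3D(np.zeros((100, 100, 100)), range_peak=1.0)
noisy = add_rician_noise(zero, RicianNoiseSpec(sigma=1.0, seed=7))
print(f"zero-signal mean {noisy.data.mean():.4f} vs sqrt(pi/2) = {np.sqrt(np.pi/2):.4f}")
const = Volume3D(np.full((100, 100, 100), 100.0))
noisy = add_rician_noise(const, RicianNoiseSpec(sigma=2.0, seed=8))
print(f"second moment {np.mean(noisy.data**2):.1f} vs A^2 + 2 sigma^2 = {100.0**2 + 8:.1f}")
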