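"""Independent naive-loop oracles for the patch-filtering operations.

Written as direct transcriptions of the voxelwise definitions — explicit
per-voxel loops over the clipped search window, explicit patch extraction from
a mirror-padded guide, explicit normalization — with no shared code, no
separable box filters and no symmetric-weight accumulation, so they can serve
as ground truth for the optimized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def naive_patch_weighted_average(
    values: np.ndarray,
    patch_guide: np.ndarray,
    h2_patch: float,
    search_radius: int,
    patch_radius: int,
    sigma_guide: np.ndarray | None = None,
    h2_sigma: float | None = None,
) -> np.ndarray:
    """Voxel-by-voxel weighted average over the clipped search window.

    w(p,q) = exp(-||N(p)-N(q)||^2 / h2_patch) [* exp(-(g(p)-g(q))^2 / h2_sigma)]
    with N(.) the (2*patch_radius+1)^3 patch of the mirror-padded guide.
    """
    shape = values.shape
    r, pr = search_radius, patch_radius
    gpad = np.pad(patch_guide, pr, mode="reflect") if pr > 0 else np.asarray(patch_guide)
    out = np.empty(shape, dtype=np.float64)
    width = 2 * pr + 1
    for p0 in range(shape[0]):
        for p1 in range(shape[1]):
            for p2 in range(shape[2]):
                patch_p = gpad[p0:p0 + width, p1:p1 + width, p2:p2 + width]
                num = 0.0
                den = 0.0
                for d0 in range(-r, r + 1):
                    q0 = p0 + d0
                    if q0 < 0 or q0 >= shape[0]:
                        continue
                    for d1 in range(-r, r + 1):
                        q1 = p1 + d1
                        if q1 < 0 or q1 >= shape[1]:
                            continue
                        for d2 in range(-r, r + 1):
                            q2 = p2 + d2
                            if q2 < 0 or q2 >= shape[2]:
                                continue
                            patch_q = gpad[q0:q0 + width, q1:q1 + width, q2:q2 + width]
                            ssd = float(((patch_p - patch_q) ** 2).sum())
                            w = math.exp(-ssd / h2_patch)
                            if sigma_guide is not None:
                                dz = sigma_guide[p0, p1, p2] - sigma_guide[q0, q1, q2]
                                w *= math.exp(-dz * dz / h2_sigma)
                            num += w * values[q0, q1, q2]
                            den += w
                out[p0, p1, p2] = num / den
    return out


def naive_block_mean(data: np.ndarray, factors) -> np.ndarray:
    """Brute-force non-overlapping block averaging (strict geometry)."""
    fx, fy, fz = factors
    nx, ny, nz = (n // f for n, f in zip(data.shape, factors))
    out = np.empty((nx, ny, nz))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                block = data[i * fx:(i + 1) * fx, j * fy:(j + 1) * fy, k * fz:(k + 1) * fz]
                out[i, j, k] = block.mean()
    return out
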