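"""Vectorized patch-similarity weighted averaging.

Shared computational core for the Rician NLM denoiser and the reference-guided
reconstruction step. For every voxel p it computes

    out(p) = (1/C_p) * sum_{q in Omega(p)} values(q) * w(p, q)

with

    w(p, q) = exp(-(g_s(p) - g_s(q))^2 / h2_sigma)          [optional sigma term]
            * exp(-||N(g_p, p) - N(g_p, q)||^2 / h2_patch)  [patch term]

where Omega(p) is the (2r+1)^3 search window clipped to the volume, N(g, .)
is the (2pr+1)^3 patch of the guide image (mirror-padded at borders), and
||.||^2 is the raw sum of squared differences over the patch (no patch-size
normalization). The centre voxel q = p contributes with weight exactly 1.

Both weight terms are symmetric under p <-> q exchange (patch SSD is symmetric
even at mirrored borders), so offsets are enumerated over a half-space and
each weight is accumulated into both endpoints — the factor-2 symmetric-weight
optimization. The update is Jacobi-style: all outputs are computed from the
frozen inputs, so the result is independent of traversal order.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["patch_weighted_average", "half_space_offsets"]


def half_space_offsets(radius: int) -> list[tuple[int, int, int]]:
    """Offsets d in [-r, r]^3 with d lexicographically greater than (0,0,0)."""
    out = []
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dz in range(-radius, radius + 1):
                if (dx, dy, dz) > (0, 0, 0):
                    out.append((dx, dy, dz))
    return out


def _overlap_slices(shape, offset):
    """Slices (sa, sb) so that arr[sa] and arr[sb] pair p with q = p + d in-bounds."""
    sa, sb = [], []
    for n, d in zip(shape, offset):
        lo, hi = max(0, -d), n - max(0, d)
        sa.append(slice(lo, hi))
        sb.append(slice(lo + d, hi + d))
    return tuple(sa), tuple(sb)


def patch_weighted_average(
    values: np.ndarray,
    patch_guide: np.ndarray,
    h2_patch: float,
    search_radius: int,
    patch_radius: int,
    sigma_guide: Optional[np.ndarray] = None,
    h2_sigma: Optional[float] = None,
) -> np.ndarray:
    """Joint sigma-filter + patch-NLM weighted average (see module docstring).

    ``values`` is the field being averaged; ``patch_guide`` supplies the patch
    SSD distances; ``sigma_guide`` (optional) supplies pointwise intensity
    distances with bandwidth ``h2_sigma``.
    """
    if search_radius < patch_radius or patch_radius < 0:
        raise ValueError(
            f"need search_radius >= patch_radius >= 0, got {search_radius}, {patch_radius}"
        )
    if h2_patch <= 0:
        raise ValueError(f"h2_patch must be > 0, got {h2_patch}")
    if (sigma_guide is None) != (h2_sigma is None):
        raise ValueError("sigma_guide and h2_sigma must be given together")
    values = np.asarray(values, dtype=np.float64)
    shape = values.shape
    r, pr = int(search_radius), int(patch_radius)
    pad = r + pr
    guide_padded = np.pad(np.asarray(patch_guide, dtype=np.float64), pad, mode="reflect")
    patch_size = 2 * pr + 1

    # centre offset: w = 1 everywhere
    num = values.copy()
    den = np.ones_like(values)

    core = tuple(slice(r, r + n + 2 * pr) for n in shape)
    interior = tuple(slice(pr, pr + n) for n in shape)
    for d in half_space_offsets(r):
        shifted = tuple(slice(r + dd, r + dd + n + 2 * pr) for dd, n in zip(d, shape))
        diff2 = (guide_padded[core] - guide_padded[shifted]) ** 2
        if pr > 0:
            ssd = uniform_filter(diff2, size=patch_size, mode="constant") * patch_size**3
        else:
            ssd = diff2
        ssd = ssd[interior]
        sa, sb = _overlap_slices(shape, d)
        expo = ssd[sa] / h2_patch
        if sigma_guide is not None:
            dz = sigma_guide[sa] - sigma_guide[sb]
            expo = expo + dz * dz / h2_sigma
        w = np.exp(-expo)
        num[sa] += w * values[sb]
        den[sa] += w
        num[sb] += w * values[sa]
        den[sb] += w
    return num / den
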