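"""Rician-adapted 3D nonlocal-means denoising.

Mandatory preprocessing before reconstruction: both the LR input and the HR
reference are denoised so that the subsampling-consistency constraint can be
applied to (nearly) noise-free data and so that reference similarities can be
computed voxelwise.

The filter is a voxelwise NLM with patch-SSD weights
``exp(-||N(p)-N(q)||^2 / h^2)``, ``h^2 = 2 * beta * sigma^2 * |patch|``.
To undo the upward bias of magnitude (Rician) data at low SNR, the filter
averages *squared* intensities and the unbiased magnitude is recovered from
the second moment: ``A = sqrt(max(E[M^2] - 2 sigma^2, 0))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from ._kernels import patch_weighted_average
from .volume import Volume3D

__all__ = ["DenoiseParams", "nlm_denoise", "nlm_average", "rician_bias_correct", "estimate_sigma"]


@dataclass(frozen=True)
class DenoiseParams:
    """NLM denoiser settings.

    search_radius / patch_radius are in voxels (defaults 3 and 1, i.e. a 7x7x7
    search window and 3x3x3 patches); sigma is the Gaussian channel standard
    deviation of the Rician noise in intensity units; beta scales the automatic
    bandwidth h^2 = 2*beta*sigma^2*|patch|.
    """

    sigma: float
    search_radius: int = 3
    patch_radius: int = 1
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not (self.search_radius >= self.patch_radius >= 0):
            raise ValueError(
                f"need search_radius >= patch_radius >= 0, got "
                f"{self.search_radius}, {self.patch_radius}"
            )
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")


def nlm_average(
    values: np.ndarray,
    guide: np.ndarray,
    h2: float,
    search_radius: int = 3,
    patch_radius: int = 1,
) -> np.ndarray:
    """Averaging stage of the denoiser: NLM weighted mean of ``values``.

    Weights come from patch SSDs of ``guide`` with bandwidth ``h2``; the search
    window is clipped at borders and patches are mirror-padded. Exposed
    separately so the averaging stage can be compared with the pure-patch limit
    of the reconstruction step.
    """
    return patch_weighted_average(values, guide, h2, search_radius, patch_radius)


def rician_bias_correct(filtered_second_moment, sigma: float):
    """Recover signal magnitude from a filtered second moment.

    A Rician variable M with underlying magnitude A satisfies
    E[M^2] = A^2 + 2 sigma^2, so A = sqrt(max(E[M^2] - 2 sigma^2, 0)); the
    clamp handles sampling fluctuations below the noise floor.
    Accepts scalars or arrays.
    """
    m2 = np.asarray(filtered_second_moment, dtype=np.float64)
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if np.any(m2 < 0):
        raise ValueError("filtered second moment must be >= 0")
    out = np.sqrt(np.maximum(m2 - 2.0 * sigma**2, 0.0))
    return float(out) if np.isscalar(filtered_second_moment) else out


def nlm_denoise(noisy: Volume3D, params: DenoiseParams) -> Volume3D:
    """Denoise a magnitude MR volume with Rician-bias-corrected NLM.

    The NLM weights are computed from the noisy intensities; the filter then
    averages squared intensities and the bias correction maps the filtered
    second moment back to signal magnitude. sigma = 0 returns the input
    unchanged.
    """
    if params.sigma == 0:
        return noisy.copy()
    patch_size = (2 * params.patch_radius + 1) ** 3
    h2 = 2.0 * params.beta * params.sigma**2 * patch_size
    second_moment = nlm_average(
        noisy.data**2, noisy.data, h2, params.search_radius, params.patch_radius
    )
    return noisy.with_data(rician_bias_correct(second_moment, params.sigma))


# 3D discrete Laplacian: centre -6, six face neighbours +1; sum of squares 42.
_LAPLACIAN = np.zeros((3, 3, 3))
_LAPLACIAN[1, 1, 1] = -6.0
for _axis_idx in ((0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)):
    _LAPLACIAN[_axis_idx] = 1.0


def estimate_sigma(noisy: Volume3D) -> float:
    """Robust noise-level estimate from high-frequency pseudo-residuals.

    Convolves with the 3D discrete Laplacian (which annihilates locally linear
    signal), takes the median absolute deviation of the residuals, scales to a
    Gaussian sigma (1.4826 * MAD) and divides by sqrt(sum of squared kernel
    weights) = sqrt(42). Approximate by design: it assumes additive noise and
    reports the Gaussian channel sigma, which for Rician data is accurate away
    from the low-SNR background.
    """
    if noisy.data.size < 1000:
        raise ValueError(f"need at least 10^3 voxels, got {noisy.data.size}")
    resid = convolve(noisy.data, _LAPLACIAN, mode="reflect")
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad / np.sqrt(42.0))
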