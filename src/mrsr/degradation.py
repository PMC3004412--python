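"""MR acquisition model: y = DHx + n.

The low-resolution (LR) volume is modeled as a decimated (D), boxcar-blurred
(H) version of the underlying high-resolution (HR) volume plus Rician noise.
Because the boxcar support matches the decimation factor and is aligned to
block origins, D and H compose into non-overlapping block averaging, which is
how the operator is implemented here. The adjoint-like nearest-neighbour
upsampling (block replication) is the NN operator used by the mean-correction
step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .volume import Volume3D

__all__ = [
    "DegradationSpec",
    "RicianNoiseSpec",
    "boxcar_downsample",
    "block_replicate_upsample",
    "add_rician_noise",
]

_BOUNDARY_MODES = ("strict", "pad_edge")


@dataclass(frozen=True)
class DegradationSpec:
    """Per-axis integer decimation factors defining D and the matched boxcar H.

    ``factors`` are the per-axis block sizes (Lx, Ly, Lz); each LR voxel is the
    mean of an Lx*Ly*Lz block of HR voxels. ``boundary_mode`` controls what
    happens when an HR dimension is not divisible by its factor: ``strict``
    raises, ``pad_edge`` edge-replicates up to the next multiple.
    """

    factors: tuple[int, int, int]
    boundary_mode: str = "strict"

    def __post_init__(self) -> None:
        factors = tuple(int(f) for f in self.factors)
        if len(factors) != 3 or any(f < 1 for f in factors):
            raise ValueError(f"factors must be three integers >= 1, got {self.factors}")
        object.__setattr__(self, "factors", factors)
        if self.boundary_mode not in _BOUNDARY_MODES:
            raise ValueError(
                f"boundary_mode must be one of {_BOUNDARY_MODES}, got {self.boundary_mode!r}"
            )

    @property
    def block_size(self) -> int:
        """Number of HR voxels averaged into one LR voxel (N = Lx*Ly*Lz)."""
        fx, fy, fz = self.factors
        return fx * fy * fz

    def lr_shape(self, hr_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple(-(-n // f) for n, f in zip(hr_shape, self.factors))  # type: ignore


@dataclass(frozen=True)
class RicianNoiseSpec:
    """Rician noise settings.

    Either ``sigma`` (Gaussian channel standard deviation, intensity units) or
    ``percent_of_max`` (noise level as % of the volume's ``range_peak``) sets
    the noise level; ``percent_of_max`` takes precedence when given.
    """

    sigma: float = 0.0
    percent_of_max: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.percent_of_max is not None and self.percent_of_max < 0:
            raise ValueError(f"percent_of_max must be >= 0, got {self.percent_of_max}")

    def effective_sigma(self, range_peak: float) -> float:
        if self.percent_of_max is not None:
            return self.percent_of_max / 100.0 * range_peak
        return self.sigma


def _padded(data: np.ndarray, factors: tuple[int, int, int], mode: str) -> np.ndarray:
    pads = []
    for axis, (n, f) in enumerate(zip(data.shape, factors)):
        rem = n % f
        if rem and mode == "strict":
            raise ValueError(
                f"dimension {n} along axis {axis} is not divisible by factor {f} "
                "(strict boundary mode)"
            )
        pads.append((0, (f - rem) % f))
    if any(p[1] for p in pads):
        data = np.pad(data, pads, mode="edge")
    return data


def boxcar_downsample(x: Volume3D, spec: DegradationSpec) -> Volume3D:
    """Apply the composed degradation DH: non-overlapping block averaging.

    Each output voxel is the arithmetic mean of its [jL, (j+1)L) HR block per
    axis; output spacing is input spacing times the factors.
    """
    fx, fy, fz = spec.factors
    data = _padded(x.data, spec.factors, spec.boundary_mode)
    nx, ny, nz = data.shape
    out = data.reshape(nx // fx, fx, ny // fy, fy, nz // fz, fz).mean(axis=(1, 3, 5))
    spacing = tuple(s * f for s, f in zip(x.spacing, spec.factors))
    vol = Volume3D(out, spacing=spacing, range_peak=x.range_peak)
    if x.affine is not None:
        aff = x.affine.copy()
        aff[:3, :3] = aff[:3, :3] * np.array(spec.factors)[None, :]
        # LR voxel 0 sits at the centre of its HR block
        aff[:3, 3] = (x.affine @ np.array([(fx - 1) / 2, (fy - 1) / 2, (fz - 1) / 2, 1.0]))[:3]
        vol.affine = aff
    return vol


def block_replicate_upsample(
    y: Volume3D, spec: DegradationSpec, out_shape: Optional[tuple[int, int, int]] = None
) -> Volume3D:
    """Nearest-neighbour upsampling: replicate each LR voxel over its HR block.

    ``out_shape`` crops the replicated volume back to a recorded HR shape
    (needed for pad_edge round trips); it defaults to ``shape * factors``.
    """
    data = y.data
    for axis, f in enumerate(spec.factors):
        if f > 1:
            data = np.repeat(data, f, axis=axis)
    if out_shape is not None:
        out_shape = tuple(int(n) for n in out_shape)
        if any(o > s or o < 1 for o, s in zip(out_shape, data.shape)):
            raise ValueError(
                f"out_shape {out_shape} incompatible with replicated shape {data.shape}"
            )
        data = data[: out_shape[0], : out_shape[1], : out_shape[2]]
    spacing = tuple(s / f for s, f in zip(y.spacing, spec.factors))
    vol = Volume3D(data.copy(), spacing=spacing, range_peak=y.range_peak)
    if y.affine is not None:
        fx, fy, fz = spec.factors
        aff = y.affine.copy()
        aff[:3, :3] = aff[:3, :3] / np.array(spec.factors)[None, :]
        aff[:3, 3] = (y.affine @ np.array(
            [-(fx - 1) / (2 * fx), -(fy - 1) / (2 * fy), -(fz - 1) / (2 * fz), 1.0]
        ))[:3]
        vol.affine = aff
    return vol


def add_rician_noise(x: Volume3D, noise: RicianNoiseSpec) -> Volume3D:
    """Corrupt a (real, non-negative) volume with Rician noise.

    Noise is generated the way magnitude MR data acquires it: the clean
    intensities are taken as the real part of a complex signal with zero
    imaginary part, i.i.d. Gaussian noise of standard deviation sigma is added
    to both channels (real channel drawn first from a single seeded stream),
    and the complex modulus is returned. sigma = 0 returns |x|.
    """
    sigma = noise.effective_sigma(x.range_peak)
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return x.with_data(np.abs(x.data))
    rng = np.random.default_rng(noise.seed)
    g_real = rng.normal(0.0, sigma, size=x.shape)
    g_imag = rng.normal(0.0, sigma, size=x.shape)
    return x.with_data(np.hypot(x.data + g_real, g_imag))
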