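"""Interpolation baselines and the misregistration shift operator.

All upsamplers share one grid-alignment convention matched to the block-mean
degradation model: the centre of LR voxel j coincides with the centre of its
HR block, i.e. HR coordinate j*L + (L-1)/2. Under this convention
nearest-neighbour interpolation is exactly block replication, and linear
interpolation of a block-averaged ramp reproduces the ramp.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .degradation import DegradationSpec, block_replicate_upsample
from .volume import Volume3D

__all__ = ["interpolate_upsample", "shift_volume", "INTERP_METHODS"]

INTERP_METHODS = ("nearest", "trilinear", "cubic", "bspline")


def _lr_coords(n_out: int, factor: int) -> np.ndarray:
    """LR-grid coordinate of each HR voxel centre along one axis."""
    return (np.arange(n_out) - (factor - 1) / 2.0) / factor


def _keys_kernel(s: np.ndarray) -> np.ndarray:
    """Cubic-convolution kernel (Keys, a = -0.5)."""
    s = np.abs(s)
    out = np.zeros_like(s)
    near = s <= 1
    far = (s > 1) & (s < 2)
    out[near] = (1.5 * s[near] - 2.5) * s[near] ** 2 + 1.0
    out[far] = ((-0.5 * s[far] + 2.5) * s[far] - 4.0) * s[far] + 2.0
    return out


def _cubic_axis(data: np.ndarray, u: np.ndarray, axis: int) -> np.ndarray:
    """Separable cubic-convolution resampling along one axis, edge-clamped."""
    n = data.shape[axis]
    base = np.floor(u).astype(int)
    t = u - base
    out = None
    for m in range(-1, 3):
        idx = np.clip(base + m, 0, n - 1)
        w = _keys_kernel(t - m)
        shape = [1, 1, 1]
        shape[axis] = len(u)
        term = np.take(data, idx, axis=axis) * w.reshape(shape)
        out = term if out is None else out + term
    return out


def interpolate_upsample(
    y: Volume3D,
    spec: DegradationSpec,
    method: str,
    out_shape: Optional[tuple[int, int, int]] = None,
) -> Volume3D:
    """Upsample an LR volume to the HR grid implied by the decimation factors.

    ``method`` is one of nearest / trilinear / cubic / bspline (order-3
    interpolating spline). ``out_shape`` overrides the default
    ``shape * factors`` HR shape (pad_edge geometries).
    """
    if method not in INTERP_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {INTERP_METHODS}")
    if method == "nearest":
        return block_replicate_upsample(y, spec, out_shape=out_shape)
    if out_shape is None:
        out_shape = tuple(n * f for n, f in zip(y.shape, spec.factors))
    axes_coords = [_lr_coords(n, f) for n, f in zip(out_shape, spec.factors)]
    if method == "cubic":
        data = y.data
        for axis, u in enumerate(axes_coords):
            data = _cubic_axis(data, u, axis)
    else:
        order = 1 if method == "trilinear" else 3
        grid = np.meshgrid(*axes_coords, indexing="ij")
        data = map_coordinates(y.data, grid, order=order, mode="nearest")
    spacing = tuple(s / f for s, f in zip(y.spacing, spec.factors))
    return Volume3D(data, spacing=spacing, range_peak=y.range_peak)


def shift_volume(
    z: Volume3D, offsets: Sequence[float], mode: str = "integer"
) -> Volume3D:
    """Translate a volume, edge-replicating at exposed borders.

    ``integer`` mode shifts by whole voxels; ``trilinear`` supports sub-voxel
    offsets. Positive offset moves content towards higher indices. Used by the
    misregistration-sensitivity protocol, where the HR reference is shifted by
    a known number of voxels before reconstruction.
    """
    offsets = tuple(float(o) for o in offsets)
    if len(offsets) != 3:
        raise ValueError(f"offsets must have three components, got {offsets}")
    for o, n in zip(offsets, z.shape):
        if abs(o) >= n:
            raise ValueError(f"offset {o} exceeds dimension {n}")
    if mode == "integer":
        if any(o != int(o) for o in offsets):
            raise ValueError(f"integer mode requires whole-voxel offsets, got {offsets}")
        data = z.data
        for axis, o in enumerate(offsets):
            idx = np.clip(np.arange(z.shape[axis]) - int(o), 0, z.shape[axis] - 1)
            data = np.take(data, idx, axis=axis)
        return z.with_data(data)
    if mode == "trilinear":
        grids = np.meshgrid(
            *[np.arange(n) - o for n, o in zip(z.shape, offsets)], indexing="ij"
        )
        return z.with_data(map_coordinates(z.data, grids, order=1, mode="nearest"))
    raise ValueError(f"mode must be 'integer' or 'trilinear', got {mode!r}")
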