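"""NIfTI-1 volume I/O."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np

from .volume import Volume3D

__all__ = ["read_volume", "write_volume"]

PathLike = Union[str, Path]


def read_volume(path: PathLike, range_peak: Optional[float] = None) -> Volume3D:
    """Load a 3D NIfTI-1 volume.

    Data is converted to float64; spacing comes from the header zooms and the
    world affine is preserved. 4D files with a trailing singleton dimension
    are accepted as 3D; genuine multi-frame files are rejected. range_peak
    defaults to the data maximum unless overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot load volume: {path} does not exist")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"cannot load volume {path}: expected 3D data "
            f"(or 4D with a singleton trailing dim), got shape {data.shape}"
        )
    if np.isnan(data).any():
        raise ValueError(f"cannot load volume {path}: data contains NaN intensities")
    zooms = img.header.get_zooms()[:3]
    return Volume3D(
        data,
        spacing=tuple(float(z) for z in zooms),
        range_peak=range_peak,
        affine=np.asarray(img.affine, dtype=np.float64),
    )


def write_volume(v: Volume3D, path: PathLike, dtype=np.float32) -> Path:
    """Write a volume as NIfTI-1 (float32 by default) with correct zooms."""
    path = Path(path)
    affine = v.affine if v.affine is not None else np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(v.data.astype(dtype), affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
    return path
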