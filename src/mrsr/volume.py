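"""Container for 3D scalar volumes.

``Volume3D`` is the universal currency of the pipeline: a 3D floating-point
intensity grid plus per-axis voxel spacing (mm) and a nominal intensity peak
``range_peak`` used for filtering-strength scaling and PSNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["Volume3D"]


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with voxel-spacing metadata.

    Parameters
    ----------
    data:
        3D array of real-valued intensities. Stored as float64 regardless of
        the source dtype.
    spacing:
        Per-axis voxel size in mm.
    range_peak:
        Nominal intensity peak (same units as ``data``). Defaults to the data
        maximum; falls back to 1.0 for non-positive volumes so that it is
        always strictly positive.
    affine:
        Optional 4x4 world-coordinate affine (preserved through NIfTI I/O).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    range_peak: Optional[float] = None
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities (NaN/Inf)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if self.range_peak is None:
            peak = float(self.data.max())
            self.range_peak = peak if peak > 0 else 1.0
        self.range_peak = float(self.range_peak)
        if self.range_peak <= 0:
            raise ValueError(f"range_peak must be > 0, got {self.range_peak}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, *, spacing=None) -> "Volume3D":
        """New volume with replaced intensities, inheriting metadata."""
        return replace(
            self,
            data=np.asarray(data, dtype=np.float64),
            spacing=self.spacing if spacing is None else tuple(spacing),
            range_peak=self.range_peak,
            affine=None if self.affine is None or spacing is not None else self.affine,
        )

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy())
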