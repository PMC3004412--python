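"""Reconstruction quality metrics: PSNR and IPSNR."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .volume import Volume3D

__all__ = ["EvalReport", "psnr", "ipsnr"]


@dataclass
class EvalReport:
    """Evaluation record for one method on one study."""

    method: str
    psnr_db: float
    ipsnr_db: Optional[float] = None
    baseline: Optional[str] = None
    params_digest: dict = field(default_factory=dict)

    @property
    def is_exact(self) -> bool:
        """True when the compared volumes were identical (infinite PSNR)."""
        return math.isinf(self.psnr_db)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "psnr_db": self.psnr_db,
            "ipsnr_db": self.ipsnr_db,
            "baseline": self.baseline,
            "params_digest": self.params_digest,
        }


def psnr(reference: Volume3D, test: Volume3D, peak: Optional[float] = None) -> float:
    """Peak signal-to-noise ratio, 10*log10(peak^2 / MSE), in dB.

    ``peak`` defaults to the reference volume's range_peak (pass 255.0 to force
    the 8-bit convention). Identical volumes return +inf.
    """
    if reference.shape != test.shape:
        raise ValueError(f"grid mismatch: {reference.shape} vs {test.shape}")
    if peak is None:
        peak = reference.range_peak
    if peak <= 0:
        raise ValueError(f"peak must be > 0, got {peak}")
    mse = float(np.mean((reference.data - test.data) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(peak * peak / mse)


def ipsnr(
    reference: Volume3D,
    proposed: Volume3D,
    baseline: Volume3D,
    peak: Optional[float] = None,
) -> float:
    """PSNR improvement of ``proposed`` over ``baseline``, in dB.

    Positive values mean the proposed reconstruction is closer to the
    reference. Antisymmetric under swapping proposed and baseline.
    """
    a = psnr(reference, proposed, peak)
    b = psnr(reference, baseline, peak)
    if math.isinf(a) and math.isinf(b):
        return 0.0
    return a - b
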