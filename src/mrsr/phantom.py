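"""Paired-contrast synthetic brain-like phantoms and simulated studies.

Generates the inputs every experiment class needs without external downloads:
a shared piecewise-constant anatomy of nested/overlapping ellipsoidal tissue
regions, mapped through two different label->intensity tables (modality A and
modality B, with inverted contrast ordering by default, emulating T1/T2-style
contrast inversion), partial-volume boundary softening by Gaussian smoothing,
optional lesions visible in only one modality (emulating lesions hyperintense
in one contrast but inconspicuous in the other), and Rician noise.

The geometry is deliberately simple; what matters for the reconstruction
method is that it preserves cross-modal structural correspondence (shared
boundaries) and intra-modal self-similarity (repeated blobs), the two
properties the method exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .degradation import (
    DegradationSpec,
    RicianNoiseSpec,
    add_rician_noise,
    boxcar_downsample,
)
from .volume import Volume3D

__all__ = ["LesionSpec", "PhantomSpec", "StudyBundle",
           "generate_multimodal_phantom", "simulate_study"]

PHANTOM_PEAK = 255.0  # phantoms are generated on the 8-bit intensity scale


@dataclass(frozen=True)
class LesionSpec:
    """Focal lesions inserted into the innermost tissue shell.

    ``visible_in`` lists the modalities ("A"/"B") where the lesion takes its
    own intensity; elsewhere lesion voxels keep the host tissue intensity.
    """

    count: int = 3
    radius_range: tuple[float, float] = (2.0, 4.0)
    visible_in: frozenset[str] = frozenset({"B"})
    intensity: Mapping[str, float] = field(default_factory=lambda: {"B": 250.0})

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("lesion count must be >= 0")
        lo, hi = self.radius_range
        if lo < 1 or hi < lo:
            raise ValueError(f"lesion radii must be >= 1 voxel, got {self.radius_range}")
        bad = self.visible_in - {"A", "B"}
        if bad:
            raise ValueError(f"visible_in entries must be 'A' or 'B', got {bad}")
        missing = self.visible_in - set(self.intensity)
        if missing:
            raise ValueError(f"lesion intensity missing for modalities {missing}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise settings for one paired-contrast phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    n_structures: int = 5
    contrast_A: Optional[Mapping[int, float]] = None
    contrast_B: Optional[Mapping[int, float]] = None
    pv_smoothing_sigma: float = 0.8
    lesion: Optional[LesionSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 8 for n in self.shape):
            raise ValueError(f"shape must be three dims >= 8, got {self.shape}")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.pv_smoothing_sigma < 0:
            raise ValueError("pv_smoothing_sigma must be >= 0")

    def labels(self) -> list[int]:
        """All tissue labels: 0 is background, 1..n_structures the regions."""
        return list(range(self.n_structures + 1))

    def default_tables(self) -> tuple[dict[int, float], dict[int, float]]:
        """Inverted-ordering default contrasts (bright-in-A is dark-in-B)."""
        n = self.n_structures
        vals_a = np.linspace(70.0, 240.0, n)
        vals_b = np.linspace(230.0, 60.0, n)
        a = {0: 5.0}
        b = {0: 5.0}
        for lab in range(1, n + 1):
            a[lab] = float(vals_a[lab - 1])
            b[lab] = float(vals_b[lab - 1])
        return a, b

    def resolved_tables(self) -> tuple[dict[int, float], dict[int, float]]:
        da, db = self.default_tables()
        ta = dict(self.contrast_A) if self.contrast_A is not None else da
        tb = dict(self.contrast_B) if self.contrast_B is not None else db
        for name, tab in (("contrast_A", ta), ("contrast_B", tb)):
            missing = set(self.labels()) - set(tab)
            if missing:
                raise ValueError(f"{name} missing entries for labels {sorted(missing)}")
            if any(not (0 <= v <= 255) for v in tab.values()):
                raise ValueError(f"{name} intensities must lie in [0, 255]")
        return ta, tb


@dataclass
class StudyBundle:
    """One simulated experiment: truth, degraded input, reference, metadata."""

    hr_truth: Volume3D
    hr_reference: Volume3D
    lr_input: Volume3D
    spec: DegradationSpec
    noise: RicianNoiseSpec
    labels: Volume3D
    lesion_mask: Optional[np.ndarray] = None


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def generate_multimodal_phantom(
    spec: PhantomSpec,
) -> tuple[Volume3D, Volume3D, Volume3D]:
    """Build the paired-contrast phantom: (modality A, modality B, labels).

    Up to four structures form nested concentric shells (head / CSF-like /
    GM-like / WM-like); any further structures are smaller random blobs placed
    inside the innermost shell, giving the self-similarity term repeated
    texture to exploit. Lesion voxels receive the dedicated label
    ``n_structures + 1`` in the returned label volume. Deterministic given the
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    labels = np.zeros(shape, dtype=np.int32)
    center0 = np.array(shape) / 2.0

    n_shells = min(spec.n_structures, 4)
    radii = np.array(shape) * 0.44
    for lab in range(1, n_shells + 1):
        center = center0 + rng.uniform(-1.5, 1.5, size=3)
        jitter = rng.uniform(0.92, 1.0, size=3)
        labels[_ellipsoid_mask(shape, center, radii * jitter)] = lab
        radii = radii * 0.78

    inner_lab = n_shells
    for lab in range(n_shells + 1, spec.n_structures + 1):
        host = np.argwhere(labels == inner_lab)
        if len(host) == 0:  # degenerate tiny grids
            host = np.argwhere(labels >= 0)
        for _ in range(3):  # a few blobs per extra structure for redundancy
            center = host[rng.integers(len(host))]
            r = rng.uniform(2.5, max(3.0, min(shape) * 0.08), size=3)
            labels[_ellipsoid_mask(shape, center, r)] = lab

    lesion_label = spec.n_structures + 1
    lesion_mask = np.zeros(shape, dtype=bool)
    if spec.lesion is not None and spec.lesion.count > 0:
        host = np.argwhere(labels == inner_lab)
        if len(host) == 0:
            raise ValueError("no host tissue available for lesion placement")
        for _ in range(spec.lesion.count):
            center = host[rng.integers(len(host))]
            r = rng.uniform(*spec.lesion.radius_range)
            lesion_mask |= _ellipsoid_mask(shape, center, (r, r, r))
        labels[lesion_mask] = lesion_label

    table_a, table_b = spec.resolved_tables()
    host_a, host_b = table_a[inner_lab], table_b[inner_lab]
    if spec.lesion is not None:
        table_a[lesion_label] = (
            float(spec.lesion.intensity["A"]) if "A" in spec.lesion.visible_in else host_a
        )
        table_b[lesion_label] = (
            float(spec.lesion.intensity["B"]) if "B" in spec.lesion.visible_in else host_b
        )

    def mapped(table: Mapping[int, float]) -> np.ndarray:
        lut = np.zeros(max(table) + 1)
        for lab, val in table.items():
            lut[lab] = val
        img = lut[labels]
        if spec.pv_smoothing_sigma > 0:
            img = gaussian_filter(img, spec.pv_smoothing_sigma, mode="nearest")
        return img

    vol_a = Volume3D(mapped(table_a), range_peak=PHANTOM_PEAK)
    vol_b = Volume3D(mapped(table_b), range_peak=PHANTOM_PEAK)
    label_vol = Volume3D(labels.astype(float), range_peak=max(float(labels.max()), 1.0))
    return vol_a, vol_b, label_vol


def simulate_study(
    pspec: PhantomSpec, dspec: DegradationSpec, noise: RicianNoiseSpec
) -> StudyBundle:
    """Simulate one experiment: degrade modality B, keep modality A as reference.

    The ground truth is the clean modality-B HR volume; the LR input is its
    block-averaged version corrupted with Rician noise; the HR reference is
    the modality-A volume corrupted at the same noise level (an independent
    noise realization), matching the protocol of adding the same noise level
    to LR and HR data.
    """
    vol_a, vol_b, label_vol = generate_multimodal_phantom(pspec)
    lesion_label = pspec.n_structures + 1
    lesion_mask = label_vol.data.astype(int) == lesion_label
    lr = add_rician_noise(boxcar_downsample(vol_b, dspec), noise)
    ref_noise = RicianNoiseSpec(
        sigma=noise.sigma,
        percent_of_max=noise.percent_of_max,
        seed=(noise.seed + 1) % 2**31,
    )
    hr_ref = add_rician_noise(vol_a, ref_noise)
    return StudyBundle(
        hr_truth=vol_b,
        hr_reference=hr_ref,
        lr_input=lr,
        spec=dspec,
        noise=noise,
        labels=label_vol,
        lesion_mask=lesion_mask if lesion_mask.any() else None,
    )
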