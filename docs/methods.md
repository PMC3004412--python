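# Methods

## Acquisition model

`mrsr` treats a low-resolution (LR) MR volume `y` as a degraded observation
of an underlying high-resolution (HR) volume `x`:

    y = DHx + n

`H` is a 3D boxcar blur whose support equals the per-axis decimation factors
(Lx, Ly, Lz) and `D` takes every L-th voxel from index zero. Because the
boxcar support matches the factors and is aligned to block origins, `DH` is
implemented directly as non-overlapping block averaging: each LR voxel is
the arithmetic mean of its Lx·Ly·Lz HR block. This is the partial-volume
model of MR: a thick-slice voxel mixes the tissue intensities of the thin
slices it spans. `n` is Rician: magnitude images inherit
`M = sqrt((A+g₁)² + g₂²)` noise from the two Gaussian-corrupted complex
channels, which biases low-SNR intensities upward (`E[M²] = A² + 2σ²`).

Dimensions not divisible by their factor are either rejected (`strict`,
default) or edge-replicated up to the next multiple (`pad_edge`); in the
latter case the upsampling operators accept an `out_shape` to crop back to
the recorded HR shape, which preserves the exact
downsample∘replicate = identity round trip.

## Preprocessing: Rician NLM denoising

The subsampling-consistency constraint (below) only makes sense on
noise-free data, so both inputs are denoised first. The denoiser is a
voxelwise 3D nonlocal-means filter: weights
`exp(−‖N(p)−N(q)‖²/h²)` over a search window of radius 3, 3×3×3 patches,
with the automatic bandwidth `h² = 2·β·σ²·|patch|` (β = 1 by default). To
remove the Rician bias the filter averages *squared* intensities and maps
the filtered second moment back through `A = sqrt(max(m₂ − 2σ², 0))`; the
clamp absorbs sampling fluctuations below the noise floor. σ may be supplied
(it is known in simulations) or estimated from the data by the median
absolute deviation of 3D discrete-Laplacian pseudo-residuals
(σ̂ = 1.4826·MAD/√42 — the Laplacian annihilates locally linear signal and
its squared-coefficient sum is 42). The estimator assumes additive
homoscedastic noise and is documented as approximate for magnitude data;
it is plumbing, not part of the method proper.

## Reconstruction

Given the denoised LR volume `y`, a denoised, rigidly registered HR
reference `z` of the same subject (any contrast) on the target grid, and
the factors, the reconstruction iterates:

1. **Joint filtering.** With the current estimate x̂ᵗ (initialized by
   nearest-neighbour interpolation of `y`),

       x̂ₚᵗ⁺¹ = (1/Cₚ) Σ_{q∈Ω(p)} x̂_qᵗ · exp(−(zₚ−z_q)²/h²)
                                        · exp(−‖N(x̂,p)−N(x̂,q)‖²/(k·h²))

   Ω(p) is the (2r+1)³ search window (r = 3) clipped at volume borders and
   including p itself (its weight is exactly 1); N(·) are 3×3×3 patches of
   the current estimate, mirror-padded at borders; the patch distance is the
   raw sum of squared differences over the 27 voxels, with no patch-size
   normalization — `k` absorbs the scale. Cₚ normalizes the *product*
   weights (a single normalization constant, not one per kernel). The update
   is Jacobi-style: all outputs are computed from the frozen x̂ᵗ, so the
   result is traversal-order independent and a naive per-voxel loop defines
   the semantics exactly. Outputs are convex combinations of window values,
   so the intensity range never expands.

2. **Mean correction.** x̂ ← x̂ − NN(DHx̂ − y), where NN is block
   replication. This projects onto the constraint DHx̂ = y; after every
   iteration the block means of x̂ reproduce `y` to float precision
   (‖DHx̂ − y‖∞ ≲ 1e-13 in practice; the tests assert ≤ 1e-10).

The filtering strength follows the decremental schedule
h = (32, 16, 8, 4, 2), one pass (filter + correction) per value, then
repeats at the final h until the mean absolute difference between
consecutive estimates drops below `tol = 0.01`, with a safety cap of 50
iterations (typical runs converge in 11–18). Both steps are deterministic;
there is no RNG anywhere in reconstruction.

### Parameters

| name | default | units | role |
|---|---|---|---|
| `search_radius` | 3 | voxels | Ω = 7×7×7; larger helps marginally at steep cost |
| `patch_radius` | 1 | voxels | 3×3×3 self-similarity patches |
| `h_schedule` | 32,16,8,4,2 | 8-bit intensity | coarse-to-fine filtering strength |
| `k` | 256 | — | reference vs. self-similarity balance; small k = robust but weakly guided, large k = strongly guided but registration-sensitive |
| `tol` | 0.01 | 8-bit intensity | MAD stopping tolerance |
| `max_iters` | 50 | — | safety cap |
| `init_method` | nearest | — | initial interpolation; the fixed point is insensitive to it |

Volumes are processed at native intensity scale: the h schedule and tol are
multiplied by `range_peak/255` (`scale_h_schedule`), which reproduces the
8-bit values exactly for 8-bit-range data and corresponds to a percentage
schedule of roughly 12/6/3/1.5/0.8% of the intensity range. `range_peak`
defaults to the volume maximum at load time. Internally the reference is
rescaled by `y.range_peak / z.range_peak` so a single h serves both weight
terms; the two inputs are assumed to be on comparable (e.g. jointly
normalized or same-quantization) scales.

### Implementation notes

The production filter enumerates search offsets over a half-space and
accumulates each weight into both endpoints: the combined weight is exactly
symmetric under p↔q (both the pointwise reference term and the patch SSD
are symmetric, including at mirrored borders, since both sum the same
squared differences), which halves the work. Patch SSDs per offset are
computed with a separable box sum over the squared shifted differences of
the mirror-padded guide. The test suite pins this optimized path to a naive
seven-nested-loop oracle at ≤ 1e-10 on unit-scale 8³ volumes; any
parallel or further-optimized variant must preserve that equivalence.

Border conventions (clipped search windows, mirror-padded patches) are
shared between the denoiser and the reconstruction step, so the step with a
constant reference degenerates exactly to the denoiser's averaging stage.

## Evaluation

PSNR = 10·log₁₀(peak²/MSE) dB, with `peak` defaulting to the reference
volume's `range_peak` (a flag forces 255); identical volumes are flagged
infinite. IPSNR is the PSNR difference to a named baseline (B-spline unless
stated). The interpolation baselines (nearest = block replication,
trilinear, cubic convolution with Keys a = −0.5, and order-3 interpolating
B-spline) all use the block-centre alignment implied by the degradation
model — the centre of LR voxel j maps to HR coordinate j·L + (L−1)/2 — so
every method is compared on identical geometry. The misregistration
protocol shifts the HR reference by whole voxels (edge-replicated) with
random signs per axis, several seeded repeats per magnitude, and reports
mean IPSNR per magnitude.

## Synthetic phantom

Experiments run on generated paired-contrast phantoms: nested ellipsoidal
shells (head / CSF-like / GM-like / WM-like) plus small random blobs inside
the innermost shell, one shared label geometry mapped through two
label→intensity tables with inverted orderings (emulating T1/T2-style
contrast inversion), Gaussian boundary smoothing (σ = 0.8 voxel) for
partial-volume softening, optional lesions visible in only a chosen subset
of modalities, and Rician noise at a chosen percentage of the intensity
peak (matching levels applied to LR and reference, independent
realizations). Phantoms are generated on the 8-bit scale with
`range_peak = 255`.

The phantom preserves the two properties the method exploits — cross-modal
structural correspondence and intra-modal self-similarity — but it is not
anatomy: it has no bias fields, no relaxometry, no texture within tissues
beyond partial-volume boundaries, and far simpler geometry than a brain.
Passing tests therefore demonstrate the algorithmic properties (consistency,
ordering against baselines, robustness trends), not clinical performance;
absolute PSNR values on the phantom are higher than one would obtain on
real brains, where self-similarity is weaker and structures finer.

## Problem sizes and numerical choices

The test suite and the acceptance script use 64³ phantoms for the
noise-free ordering and initialization-invariance experiments and 48³ for
the noise- and misregistration-sensitivity sweeps (the sweeps run 4 and 11
full reconstructions respectively); these sizes give stable, well-separated
results while keeping a full run in minutes on one CPU. Oracle-equivalence
checks use 8³ unit-scale volumes so the 1e-10 absolute bound is meaningful
against float64 summation-order differences. Ties and degenerate cases:
constant volumes are fixed points of every stage; σ = 0 short-circuits the
denoiser and the noise generator (returning |x|); `rician_bias_correct`
clamps at zero; PSNR of identical volumes is reported as infinite rather
than raising.

## Limitations

- Registration is a precondition; the method tolerates ~1–2 voxels of
  residual shift (IPSNR stays positive) but degrades beyond that.
- The boxcar slice profile is an approximation; Gaussian profiles or slice
  gaps are not modeled.
- The denoiser is a voxelwise Rician NLM; blockwise aggregation speedups
  and spatially varying noise maps are out of scope.
- Non-integer resolution ratios are not supported — factors are per-axis
  integers.
- The noise estimator assumes homoscedastic additive noise and
  underestimates slightly on structured data; supply σ when it is known.
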