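# mrsr — reference-guided superresolution for 3D MR volumes

In routine MR studies, some volumes are acquired with thick slices (e.g.
1 × 1 × 3 mm T2-w or FLAIR) alongside a high-resolution (HR) volume of
another contrast (e.g. 1 mm³ T1-w) of the same subject. Classical
interpolation can resample the low-resolution (LR) volume onto the HR grid
but cannot restore the high-frequency content lost at acquisition. `mrsr`
implements an iterative single-image superresolution method that recovers
that detail by borrowing voxel-similarity structure from the coplanar HR
reference, while keeping the result *physically consistent* with the MR
acquisition model. It is aimed at neuroimaging pipelines (multimodal
segmentation, registration, fMRI/DTI upsampling) that need an HR version of
an anisotropic acquisition.

## The model

Acquisition is modeled as `y = DHx + n`, where `H` is a 3D boxcar blur
(every LR voxel is the mean of its Lx × Ly × Lz block of HR voxels — the
partial-volume model), `D` is decimation by the same factors, and `n` is
Rician noise. After denoising both inputs with a Rician-bias-corrected
nonlocal-means (NLM) filter, the reconstruction x̂ alternates two steps:

1. **Reconstruction.** Each voxel becomes a weighted average over a 7×7×7
   search window Ω, the weights combining a sigma filter on the denoised HR
   reference `z` with an NLM patch kernel on the current estimate:

       x̂ₚᵗ⁺¹ = (1/Cₚ) Σ_{q∈Ω} x̂_qᵗ · exp(−(zₚ−z_q)²/h²) · exp(−‖N(x̂ₚᵗ)−N(x̂_qᵗ)‖²/(k·h²))

   with 3×3×3 patches `N(·)`, normalization `Cₚ`, and `k = 256` balancing
   reference guidance against LR self-similarity (which keeps the method
   robust to small misregistrations and to features visible in only one
   contrast, such as lesions).

2. **Mean correction.** The estimate is projected back onto the
   subsampling-consistency constraint `DHx̂ = y`:

       x̂ᵗ⁺¹ ← x̂ᵗ⁺¹ − NN(DHx̂ᵗ⁺¹ − y)

   where NN is nearest-neighbour (block-replication) upsampling. After every
   iteration the block means of the reconstruction reproduce the LR input to
   float precision.

The filtering strength follows a coarse-to-fine schedule
h = 32, 16, 8, 4, 2 (8-bit scale, rescaled linearly for other ranges), one
pass per value, then iterates at h = 2 until the mean absolute difference
between consecutive estimates falls below `tol = 0.01`.

The package also provides the degradation model itself, the Rician NLM
denoiser, interpolation baselines (nearest, trilinear, cubic, B-spline) on
the matched block-centre geometry, PSNR/IPSNR evaluation, a paired-contrast
synthetic brain phantom generator for fully self-contained experiments, and
NIfTI-1 I/O.

## Worked example

`python examples/03_superresolve_study.py` simulates a 64³ paired-contrast
phantom study in which modality B was acquired with doubled slice thickness,
then reconstructs it guided by the modality-A HR volume:

```
truth (64, 64, 64), LR input (64, 64, 32), reference (64, 64, 64)
converged after 11 iterations (final MAD 0.0099 < tol 0.01)
PSNR nearest :  30.98 dB
PSNR bspline :  41.10 dB
PSNR proposed:  55.58 dB
subsampling-consistency residual ||DHx - y||_inf = 2.84e-14
```

The proposed reconstruction is ~14 dB closer to the ground truth than the
best interpolation baseline, and its residual under the acquisition model is
at float precision — downsampling the result returns the acquired LR data
exactly. The other examples demonstrate the degradation model and noise
statistics (`01`), the denoiser (`02`), and misregistration robustness
(`04`).

A thin CLI wraps the same functions:

```sh
mrsr simulate --out-dir study --shape 64,64,64 --factors 1,1,2
mrsr reconstruct --lr study/lr_input.nii.gz --ref study/hr_reference.nii.gz \
     --out recon.nii.gz --factors 1,1,2 --save-state state.json
mrsr evaluate --ref study/hr_truth.nii.gz --test recon.nii.gz --report eval.json
```

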