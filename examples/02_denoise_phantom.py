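"""Rician-bias-corrected NLM denoising on a noisy phantom.

Generates a paired-contrast phantom, corrupts one modality at 3% Rician
noise, denoises it, and reports PSNR before and after. A higher denoised
PSNR means the filter removed noise without destroying structure.
"""

from mrsr import (
    DegradationSpec,
    DenoiseParams,
    PhantomSpec,
    RicianNoiseSpec,
    estimate_sigma,
    nlm_denoise,
    psnr,
    simulate_study,
)

bundle = simulate_study(
    PhantomSpec(shape=(48, 48, 48), seed=11),
    DegradationSpec((1, 1, 1)),          # no downsampling: isolate the denoiser
    RicianNoiseSpec(percent_of_max=3.0, seed=12),
)
sigma_true = bundle.noise.effective_sigma(bundle.hr_truth.range_peak)
sigma_est = estimate_sigma(bundle.lr_input)
print(f"true sigma {sigma_true:.2f}, estimated from the data {sigma_est:.2f}")

denoised = nlm_denoise(bundle.lr_input, DenoiseParams(sigma=sigma_true))
print(f"PSNR noisy    vs truth: {psnr(bundle.hr_truth, bundle.lr_input):.2f} dB")
print(f"PSNR denoised vs truth: {psnr(bundle.hr_truth, denoised):.2f} dB")
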