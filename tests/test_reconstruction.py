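"""Iterative reconstruction: step oracle, mean correction, full loop."""

import numpy as np
import pytest
from scipy.ndimage import maximum_filter, minimum_filter

from mrsr import (
    DegradationSpec,
    SRParams,
    Volume3D,
    block_replicate_upsample,
    boxcar_downsample,
    interpolate_upsample,
    mean_correction,
    nlm_average,
    psnr,
    reconstruction_step,
    scale_h_schedule,
    simulate_study,
    superresolve,
)
from oracles import naive_patch_weighted_average


@pytest.fixture
def pair(rng):
    """Random unit-scale estimate / reference pair on an 8^3 grid."""
    x = Volume3D(rng.random((8, 8, 8)), range_peak=1.0)
    z = Volume3D(rng.random((8, 8, 8)), range_peak=1.0)
    return x, z


class TestReconstructionStep:
    def test_constant_inputs_are_fixed_point(self):
        x = Volume3D(np.full((8, 8, 8), 4.0))
        z = Volume3D(np.full((8, 8, 8), 9.0))
        out = reconstruction_step(x, z, SRParams(), h=0.5)
        np.testing.assert_allclose(out.data, 4.0, atol=1e-12)

    def test_constant_reference_reduces_to_patch_nlm(self, rng):
        # with z constant the sigma term is 1 everywhere; the step must equal
        # the denoiser's averaging stage with bandwidth k*h^2
        x = Volume3D(rng.random((8, 8, 8)), range_peak=1.0)
        z = Volume3D(np.full((8, 8, 8), 0.3), range_peak=1.0)
        params = SRParams(k=4.0)
        h = 0.2
        stepped = reconstruction_step(x, z, params, h)
        pure = nlm_average(x.data, x.data, params.k * h * h,
                           params.search_radius, params.patch_radius)
        assert np.abs(stepped.data - pure).max() <= 1e-10

    @pytest.mark.parametrize("radius", [1, 3])
    def test_matches_naive_seven_loop_oracle(self, pair, radius):
        x, z = pair
        params = SRParams(search_radius=radius, k=16.0)
        h = 0.15
        ours = reconstruction_step(x, z, params, h)
        oracle = naive_patch_weighted_average(
            x.data, x.data, params.k * h * h, radius, params.patch_radius,
            sigma_guide=z.data, h2_sigma=h * h,
        )
        assert np.abs(ours.data - oracle).max() <= 1e-10

    def test_output_is_convex_combination_of_window(self, pair):
        x, z = pair
        r = 3
        out = reconstruction_step(x, z, SRParams(search_radius=r), h=0.1)
        size = 2 * r + 1
        lo = minimum_filter(x.data, size=size, mode="nearest")
        hi = maximum_filter(x.data, size=size, mode="nearest")
        assert np.all(out.data >= lo - 1e-12)
        assert np.all(out.data <= hi + 1e-12)
        assert out.data.min() >= x.data.min() - 1e-12
        assert out.data.max() <= x.data.max() + 1e-12

    def test_grid_mismatch_and_bad_h_rejected(self, pair):
        x, _ = pair
        z_small = Volume3D(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="mismatch"):
            reconstruction_step(x, z_small, SRParams(), h=1.0)
        with pytest.raises(ValueError):
            reconstruction_step(x, x, SRParams(), h=0.0)


class TestMeanCorrection:
    def test_consistent_input_unchanged(self, rng):
        spec = DegradationSpec((1, 1, 2))
        y = Volume3D(rng.random((4, 4, 4)))
        x = block_replicate_upsample(y, spec)
        out = mean_correction(x, y, spec)
        np.testing.assert_allclose(out.data, x.data, atol=1e-13)

    def test_enforces_subsampling_consistency(self, rng):
        spec = DegradationSpec((1, 1, 2))
        x = Volume3D(rng.random((6, 6, 8)))
        y = Volume3D(rng.random((6, 6, 4)))
        out = mean_correction(x, y, spec)
        resid = boxcar_downsample(out, spec).data - y.data
        assert np.abs(resid).max() <= 1e-10

    def test_grid_mismatch_rejected(self, rng):
        spec = DegradationSpec((1, 1, 2))
        x = Volume3D(rng.random((6, 6, 8)))
        y = Volume3D(rng.random((6, 6, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            mean_correction(x, y, spec)


class TestScaleHSchedule:
    def test_identity_at_8bit_range(self):
        assert scale_h_schedule([32, 16, 8, 4, 2], 255.0) == [32, 16, 8, 4, 2]

    def test_linear_scaling(self):
        assert scale_h_schedule([32, 16, 8, 4, 2], 510.0) == [64, 32, 16, 8, 4]

    def test_non_positive_range_rejected(self):
        with pytest.raises(ValueError):
            scale_h_schedule([32.0], 0.0)


class TestSuperresolve:
    def test_constant_study_is_fixed_point(self):
        spec = DegradationSpec((2, 2, 2))
        c = 42.0
        hr = Volume3D(np.full((8, 8, 8), c), range_peak=255.0)
        y = boxcar_downsample(hr, spec)
        z = Volume3D(np.full((8, 8, 8), 100.0), range_peak=255.0)
        x, state = superresolve(y, z, spec)
        np.testing.assert_allclose(x.data, c, atol=1e-10)
        assert state.iteration == len(SRParams().h_schedule)  # converged in one pass

    def test_phantom_beats_bspline_and_converges(self, small_bundle):
        b = small_bundle
        x, state = superresolve(b.lr_input, b.hr_reference, b.spec)
        # subsampling consistency
        resid = boxcar_downsample(x, b.spec).data - b.lr_input.data
        assert np.abs(resid).max() <= 1e-10
        # convergence bookkeeping
        assert state.converged
        assert state.mad_history[-1] < state.tol_used
        assert state.iteration <= SRParams().max_iters
        # schedule: one pass per listed h, then terminal-h iterations
        sched = scale_h_schedule(SRParams().h_schedule, b.lr_input.range_peak)
        assert state.h_history[: len(sched)] == pytest.approx(sched)
        assert all(h == sched[-1] for h in state.h_history[len(sched):])
        # quality ordering against the interpolation baseline
        bsp = interpolate_upsample(b.lr_input, b.spec, "bspline")
        assert psnr(b.hr_truth, x) > psnr(b.hr_truth, bsp)

    def test_deterministic(self, small_bundle):
        b = small_bundle
        x1, _ = superresolve(b.lr_input, b.hr_reference, b.spec)
        x2, _ = superresolve(b.lr_input, b.hr_reference, b.spec)
        np.testing.assert_array_equal(x1.data, x2.data)

    def test_bad_inputs_rejected(self, small_bundle):
        b = small_bundle
        with pytest.raises(ValueError):
            SRParams(h_schedule=(2.0, 4.0))  # not decreasing
        with pytest.raises(ValueError, match="incompatib"):
            superresolve(b.lr_input, b.lr_input, b.spec)
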