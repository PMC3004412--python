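"""Interpolation baselines, PSNR/IPSNR, and the shift operator."""

import math

import numpy as np
import pytest

from mrsr import (
    DegradationSpec,
    RicianNoiseSpec,
    Volume3D,
    add_rician_noise,
    block_replicate_upsample,
    boxcar_downsample,
    interpolate_upsample,
    ipsnr,
    psnr,
    shift_volume,
)

METHODS = ("nearest", "trilinear", "cubic", "bspline")


class TestInterpolateUpsample:
    def test_nearest_is_block_replication(self, rng):
        y = Volume3D(rng.random((4, 4, 4)))
        spec = DegradationSpec((1, 2, 3))
        a = interpolate_upsample(y, spec, "nearest")
        b = block_replicate_upsample(y, spec)
        np.testing.assert_array_equal(a.data, b.data)

    @pytest.mark.parametrize("method", METHODS)
    def test_constants_are_reproduced(self, method):
        y = Volume3D(np.full((4, 4, 4), 3.75))
        out = interpolate_upsample(y, DegradationSpec((2, 2, 2)), method)
        assert out.shape == (8, 8, 8)
        np.testing.assert_allclose(out.data, 3.75, atol=1e-10)

    def test_trilinear_exact_on_block_averaged_ramp(self):
        # degrading an affine ramp gives its block-centre samples, so linear
        # interpolation on the shared alignment reproduces the ramp away from borders
        nz = 16
        ramp = np.broadcast_to(np.arange(nz, dtype=float), (4, 4, nz)).copy()
        hr = Volume3D(ramp)
        spec = DegradationSpec((1, 1, 2))
        lr = boxcar_downsample(hr, spec)
        up = interpolate_upsample(lr, spec, "trilinear")
        np.testing.assert_allclose(up.data[:, :, 1:-1], ramp[:, :, 1:-1], atol=1e-12)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown method"):
            interpolate_upsample(Volume3D(rng.random((4, 4, 4))),
                                 DegradationSpec((1, 1, 2)), "sinc")

    @pytest.mark.parametrize("method", METHODS)
    def test_out_shape_crops_pad_edge_geometry(self, rng, method):
        y = Volume3D(rng.random((4, 4, 3)))
        spec = DegradationSpec((1, 1, 2), "pad_edge")
        out = interpolate_upsample(y, spec, method, out_shape=(4, 4, 5))
        assert out.shape == (4, 4, 5)


class TestPsnr:
    def test_identical_volumes_are_flagged_infinite(self, random_volume):
        assert math.isinf(psnr(random_volume, random_volume))

    def test_constant_full_scale_error_is_zero_db(self):
        ref = Volume3D(np.full((4, 4, 4), 255.0), range_peak=255.0)
        test = Volume3D(np.zeros((4, 4, 4)))
        assert psnr(ref, test, peak=255.0) == pytest.approx(0.0, abs=1e-12)

    def test_unit_mse_at_8bit_peak(self, rng):
        ref = Volume3D(np.full((10, 10, 10), 100.0), range_peak=255.0)
        err = rng.choice([-1.0, 1.0], size=(10, 10, 10))
        test = ref.with_data(ref.data + err)  # MSE exactly 1
        assert psnr(ref, test, peak=255.0) == pytest.approx(48.1308, abs=1e-3)

    def test_decreases_with_noise_level(self, rng):
        ref = Volume3D(np.full((32, 32, 32), 100.0), range_peak=255.0)
        values = [
            psnr(ref, add_rician_noise(ref, RicianNoiseSpec(sigma=s, seed=4)))
            for s in (1.0, 3.0, 9.0)
        ]
        assert values[0] > values[1] > values[2]

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            psnr(Volume3D(rng.random((4, 4, 4))), Volume3D(rng.random((4, 4, 5))))


class TestIpsnr:
    def test_zero_when_proposed_equals_baseline(self, rng, random_volume):
        ref = Volume3D(rng.random((8, 8, 8)))
        assert ipsnr(ref, random_volume, random_volume) == 0.0

    def test_infinite_when_proposed_exact(self, rng, random_volume):
        assert math.isinf(ipsnr(random_volume, random_volume,
                                Volume3D(rng.random((8, 8, 8)))))

    def test_ten_db_for_tenfold_mse_ratio(self):
        ref = Volume3D(np.zeros((10, 10, 10)), range_peak=255.0)
        prop = ref.with_data(np.full(ref.shape, 1.0))      # MSE 1
        base = ref.with_data(np.full(ref.shape, np.sqrt(10.0)))  # MSE 10
        assert ipsnr(ref, prop, base) == pytest.approx(10.0, abs=1e-10)

    def test_antisymmetric(self, rng):
        ref = Volume3D(rng.random((8, 8, 8)))
        a = Volume3D(rng.random((8, 8, 8)))
        b = Volume3D(rng.random((8, 8, 8)))
        assert ipsnr(ref, a, b) == pytest.approx(-ipsnr(ref, b, a), abs=1e-12)


class TestShiftVolume:
    def test_zero_shift_is_identity(self, random_volume):
        out = shift_volume(random_volume, (0, 0, 0))
        np.testing.assert_array_equal(out.data, random_volume.data)

    def test_integer_shift_roundtrip_away_from_border(self, rng):
        v = Volume3D(rng.random((10, 10, 10)))
        fwd = shift_volume(v, (2, -1, 1))
        back = shift_volume(fwd, (-2, 1, -1))
        m = 2
        np.testing.assert_array_equal(
            back.data[m:-m, m:-m, m:-m], v.data[m:-m, m:-m, m:-m]
        )

    def test_constant_volume_invariant(self):
        v = Volume3D(np.full((8, 8, 8), 2.5))
        for mode, off in (("integer", (1, 2, -3)), ("trilinear", (0.5, -1.25, 2.0))):
            np.testing.assert_allclose(shift_volume(v, off, mode).data, 2.5, atol=1e-12)

    def test_subvoxel_matches_integer_at_whole_offsets(self, rng):
        v = Volume3D(rng.random((8, 8, 8)))
        a = shift_volume(v, (1, 0, -2), "integer")
        b = shift_volume(v, (1.0, 0.0, -2.0), "trilinear")
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_excessive_offset_rejected(self, random_volume):
        with pytest.raises(ValueError):
            shift_volume(random_volume, (0, 0, 8))
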