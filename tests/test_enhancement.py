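import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dbtcad import (
    BandPassFilterSpec,
    ObjectnessParams,
    Volume,
    build_bandpass_kernel,
    compute_mor,
    gaussian_smooth,
    hessian_eigenvalues,
    multiscale_objectness,
    objectness_response,
    snr_enhance,
)
from dbtcad.errors import ValidationError

CORRECTED = ObjectnessParams(mode="blobness_corrected")
AS_PRINTED = ObjectnessParams(mode="as_printed")


def _gaussian_blob(n, h, s, amplitude=100.0):
    ax = (np.arange(n) - n // 2) * h
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return Volume(amplitude * np.exp(-(X**2 + Y**2 + Z**2) / (2 * s * s)), (h, h, h))


class TestGaussianSmooth:
    def test_constant_preserved(self):
        v = Volume(np.full((8, 8, 8), 3.7), spacing=(0.5, 0.5, 2.0))
        out = gaussian_smooth(v, 1.0)
        np.testing.assert_allclose(out.data, 3.7, rtol=1e-10)

    def test_impulse_mass_preserved(self):
        v = Volume(np.zeros((21, 21, 21)), spacing=(1.0, 1.0, 1.0))
        v.data[10, 10, 10] = 5.0
        out = gaussian_smooth(v, 2.0)
        assert out.data.sum() == pytest.approx(5.0, rel=1e-6)

    def test_blob_width_adds_in_quadrature(self):
        # smoothing a Gaussian of width s with sigma gives width sqrt(s^2+sigma^2);
        # the center amplitude scales by (s^2/(s^2+sigma^2))^(3/2)
        s, sig, h = 1.0, 0.5, 0.0625
        v = _gaussian_blob(97, h, s)
        out = gaussian_smooth(v, sig)
        c = 97 // 2
        expected_center = 100.0 * (s * s / (s * s + sig * sig)) ** 1.5
        assert out.data[c, c, c] == pytest.approx(expected_center, rel=1e-3)

    @pytest.mark.parametrize("h", [0.25, 0.5])
    def test_physical_sigma_independent_of_grid_pitch(self, h):
        # an impulse smoothed with sigma_mm spreads to the same *physical*
        # width regardless of the voxel pitch along that axis
        n = int(16 / h) + 1
        data = np.zeros((n, 5, 5))
        data[n // 2, 2, 2] = 1.0
        out = gaussian_smooth(Volume(data, (h, 1.0, 1.0)), 1.5)
        profile = out.data[:, 2, 2]
        x = (np.arange(n) - n // 2) * h
        sigma_measured = np.sqrt((profile * x * x).sum() / profile.sum())
        assert sigma_measured == pytest.approx(1.5, rel=2e-2)

    def test_invalid_sigma(self):
        with pytest.raises(ValidationError):
            gaussian_smooth(Volume(np.zeros((4, 4, 4))), 0.0)


class TestHessianEigenvalues:
    def test_constant_volume_gives_zeros(self):
        v = Volume(np.full((6, 6, 6), 2.0), spacing=(0.3, 0.3, 1.0))
        eig = hessian_eigenvalues(v, 0.5)
        np.testing.assert_allclose(eig, 0.0, atol=1e-9)

    def test_isotropic_blob_closed_form(self):
        s, sig, h, A = 1.0, 0.5, 0.125, 100.0
        v = _gaussian_blob(65, h, s, A)
        eig = hessian_eigenvalues(v, sig)
        c = 65 // 2
        t2 = s * s + sig * sig
        expected = -A * (s * s / t2) ** 1.5 / t2
        np.testing.assert_allclose(eig[c, c, c], expected, rtol=5e-3)
        # spherical symmetry: three equal eigenvalues
        spread = np.ptp(eig[c, c, c]) / abs(expected)
        assert spread < 1e-6

    def test_cylindrical_ridge_has_one_null_eigenvalue(self):
        # 2D Gaussian extruded along z: lam1 = lam2 < 0, lam3 ~ 0
        s, sig, h, A = 1.0, 0.5, 0.125, 100.0
        n = 65
        ax = (np.arange(n) - n // 2) * h
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        ridge = A * np.exp(-(X**2 + Y**2) / (2 * s * s))
        v = Volume(np.repeat(ridge[:, :, None], 9, axis=2), (h, h, h))
        eig = hessian_eigenvalues(v, sig)
        lam = eig[n // 2, n // 2, 4]
        t2 = s * s + sig * sig
        expected_perp = -A * (s * s / t2) / t2  # 2D amplitude factor
        np.testing.assert_allclose(lam[:2], expected_perp, rtol=5e-3)
        assert abs(lam[2]) < 1e-3 * abs(expected_perp)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValidationError):
            hessian_eigenvalues(Volume(np.zeros((2, 5, 5))), 1.0)


class TestObjectnessResponse:
    def test_equal_negative_eigenvalues_spot_value(self):
        # (1-exp(-1/0.02)) * (1-exp(-3/18)) with alpha=0.1, gamma=3.0
        expected = (1 - np.exp(-50.0)) * (1 - np.exp(-1.0 / 6.0))
        for p in (CORRECTED, AS_PRINTED):
            assert float(objectness_response(np.array([-1.0, -1.0, -1.0]), p)) == pytest.approx(
                expected, abs=1e-9
            )

    @pytest.mark.parametrize(
        "eigs, mode, expected",
        [
            ((-1.0, -1.0, 0.0), "blobness_corrected", 0.0),  # ideal bright line
            ((-1.0, 0.0, 0.0), "blobness_corrected", 0.0),  # ideal bright plane
            ((0.0, 0.0, 0.0), "blobness_corrected", 0.0),
            ((0.0, 0.0, 0.0), "as_printed", 0.0),
            ((-1.0, -2.0, 1.0), "blobness_corrected", 0.0),  # lam3 > 0 gate
            ((-1.0, -2.0, 1.0), "as_printed", 0.0),
        ],
    )
    def test_degenerate_and_gated_cases(self, eigs, mode, expected):
        p = ObjectnessParams(mode=mode)
        assert float(objectness_response(np.array(eigs), p)) == pytest.approx(expected, abs=1e-12)

    def test_as_printed_saturates_on_lines(self):
        # the printed shape ratio blows up as lam3 -> 0-, so an ideal line
        # keeps the full structureness weight in as_printed mode
        resp = float(objectness_response(np.array([-1.0, -1.0, 0.0]), AS_PRINTED))
        assert resp == pytest.approx(1 - np.exp(-2.0 / 18.0), abs=1e-9)

    @given(
        eigs=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        perm=st.permutations([0, 1, 2]),
        mode=st.sampled_from(["as_printed", "blobness_corrected"]),
    )
    def test_invariant_to_presentation_order(self, eigs, perm, mode):
        p = ObjectnessParams(mode=mode)
        e = np.array(eigs)
        assert float(objectness_response(e, p)) == float(objectness_response(e[list(perm)], p))

    @given(a=st.floats(0.01, 100), c=st.floats(1.0, 10.0))
    def test_sphere_positive_lines_planes_zero_at_all_magnitudes(self, a, c):
        sphere = np.array([-a, -a, -a])
        line = np.array([-a, -a, 0.0])
        plane = np.array([-a, 0.0, 0.0])
        assert float(objectness_response(sphere, CORRECTED)) > 0
        assert float(objectness_response(line, CORRECTED)) == 0
        assert float(objectness_response(plane, CORRECTED)) == 0
        # scaling up never decreases the response (structureness monotone,
        # shape ratio scale-invariant)
        assert float(objectness_response(c * sphere, CORRECTED)) >= float(
            objectness_response(sphere, CORRECTED)
        )

    def test_param_validation(self):
        with pytest.raises(ValidationError):
            ObjectnessParams(alpha=0.0)
        with pytest.raises(ValidationError):
            ObjectnessParams(scales=(1.0, 1.0))
        with pytest.raises(ValidationError):
            ObjectnessParams(mode="frangi")


class TestMultiscaleObjectness:
    def test_single_scale_degenerate_case(self, rng):
        v = Volume(rng.normal(size=(10, 10, 6)), spacing=(1, 1, 1))
        p1 = ObjectnessParams(scales=(0.8,))
        out = multiscale_objectness(v, p1)
        ref = objectness_response(hessian_eigenvalues(v, 0.8), p1)
        np.testing.assert_array_equal(out.data, ref)

    def test_equals_pointwise_max_over_scales(self, rng):
        v = Volume(rng.normal(size=(12, 12, 8)), spacing=(1, 1, 1))
        p = ObjectnessParams(scales=(0.6, 1.0, 1.6))
        out = multiscale_objectness(v, p)
        singles = [
            objectness_response(hessian_eigenvalues(v, s), p) for s in p.scales
        ]
        np.testing.assert_allclose(out.data, np.max(singles, axis=0), rtol=1e-12)

    def test_blob_phantom_argmax_at_blob(self, clean_blob_line_phantom):
        from dbtcad import subsample_xy

        cfg, (vol, truth) = clean_blob_line_phantom
        sub = subsample_xy(vol, 10)
        O = multiscale_objectness(sub, CORRECTED)
        peak_idx = np.array(np.unravel_index(np.argmax(O.data), O.shape))
        peak_mm = peak_idx * np.array(sub.spacing) + np.array(sub.origin)
        blob_mm = truth.mcs[0].center_mm
        assert np.all(np.abs(peak_mm - blob_mm) <= np.array(sub.spacing) + 1e-9)


class TestBandPassKernel:
    def test_default_weights(self):
        k = build_bandpass_kernel(BandPassFilterSpec(15, 7, 3))
        w = k.weights
        assert w.shape == (15, 15)
        assert abs(w.sum()) < 1e-12
        c = 7
        np.testing.assert_allclose(w[c - 1 : c + 2, c - 1 : c + 2], 1.0 / 9.0)
        assert w[0, 0] == pytest.approx(-1.0 / 176.0)
        # guard ring between M3 and M2 is zero
        assert w[c - 3, c] == 0.0

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValidationError):
            BandPassFilterSpec(7, 15, 3)
        with pytest.raises(ValidationError):
            BandPassFilterSpec(15, 8, 3)

    @given(
        ms=st.lists(st.integers(0, 12), min_size=3, max_size=3, unique=True).map(
            lambda v: tuple(2 * m + 1 for m in sorted(v, reverse=True))
        )
    )
    def test_zero_sum_and_symmetry_for_any_valid_spec(self, ms):
        k = build_bandpass_kernel(BandPassFilterSpec(*ms))
        w = k.weights
        assert abs(w.sum()) < 1e-10
        np.testing.assert_array_equal(w, np.rot90(w))
        np.testing.assert_array_equal(w, w[::-1, :])
        np.testing.assert_array_equal(w, w.T)


class TestSnrEnhance:
    def test_constant_slices_give_zero(self):
        v = Volume(np.full((20, 20, 3), 7.0), spacing=(0.1, 0.1, 1.0))
        out = snr_enhance(v, BandPassFilterSpec())
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_impulse_response_peak_and_clamped_ring(self):
        v = Volume(np.zeros((31, 31, 1)))
        v.data[15, 15, 0] = 1.0
        out = snr_enhance(v, build_bandpass_kernel(BandPassFilterSpec()))
        assert out.data[15, 15, 0] == pytest.approx(1.0 / 9.0)
        # annulus response is negative, hence clamped to 0
        assert out.data[15, 8, 0] == 0.0

    def test_box_decomposition_matches_explicit_kernel(self, rng):
        v = Volume(rng.normal(size=(25, 25, 2)))
        spec = BandPassFilterSpec(9, 5, 3)
        fast = snr_enhance(v, spec)
        direct = snr_enhance(v, build_bandpass_kernel(spec))
        np.testing.assert_allclose(fast.data, direct.data, atol=1e-10)

    def test_slices_processed_independently(self, rng):
        slc = rng.normal(size=(20, 20))
        v = Volume(np.stack([slc, slc], axis=2))
        out = snr_enhance(v, BandPassFilterSpec())
        np.testing.assert_array_equal(out.data[:, :, 0], out.data[:, :, 1])

    def test_shift_equivariance_away_from_boundary(self, rng):
        base = np.zeros((48, 48, 1))
        base[20:24, 20:24, 0] = rng.normal(size=(4, 4))
        shifted = np.roll(base, (3, 2), axis=(0, 1))
        spec = BandPassFilterSpec()
        out_a = snr_enhance(Volume(base), spec).data
        out_b = snr_enhance(Volume(shifted), spec).data
        np.testing.assert_allclose(
            np.roll(out_a, (3, 2), axis=(0, 1))[10:38, 10:38], out_b[10:38, 10:38], atol=1e-10
        )

    def test_slice_smaller_than_kernel_rejected(self):
        with pytest.raises(ValidationError):
            snr_enhance(Volume(np.zeros((10, 10, 2))), BandPassFilterSpec())


class TestComputeMor:
    def test_zero_snr_absorbs(self, rng):
        o = Volume(rng.uniform(size=(6, 6, 3)))
        z = o.with_data(np.zeros(o.shape))
        np.testing.assert_array_equal(compute_mor(o, z).data, 0.0)

    def test_unit_snr_is_identity(self, rng):
        o = Volume(rng.uniform(size=(6, 6, 3)))
        ones = o.with_data(np.ones(o.shape))
        np.testing.assert_array_equal(compute_mor(o, ones).data, o.data)

    def test_product_bound(self, rng):
        o = Volume(rng.uniform(size=(6, 6, 3)))
        s = o.with_data(rng.uniform(size=(6, 6, 3)))
        mor = compute_mor(o, s)
        assert mor.data.max() <= o.data.max() * s.data.max() + 1e-12

    def test_grid_mismatch_rejected(self, rng):
        o = Volume(rng.uniform(size=(6, 6, 3)), spacing=(1, 1, 1))
        s = Volume(rng.uniform(size=(6, 6, 3)), spacing=(2, 2, 1))
        with pytest.raises(ValidationError):
            compute_mor(o, s)
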