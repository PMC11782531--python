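"""Linearization correction, brighter-fatter kernels and the BRE check."""

import numpy as np
import pytest

from ccdnoise.calibration import (
    apply_gain_reference,
    build_gain_reference,
    dark_subtract,
    estimate_kref_autocov,
)
from ccdnoise.correlation import cconv2, rho_from_kernel
from ccdnoise.linearity import (
    BFCurve,
    NonlinearityFit,
    bf_kernel_2d,
    bf_psf_from_beta,
    bre_linearity_check,
    estimate_bf_curve,
    fit_pade_45,
    g_lin,
    total_variance_model,
)
from ccdnoise.simulate import BeamModel, DetectorModel, simulate_dark, simulate_frame

T = 0.84
FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


class TestGLin:
    def test_zero_polynomial_is_identity(self):
        fit = NonlinearityFit(0.0, 0.0, 0.0, 1.55, 7000.0)
        xi = np.linspace(100, 60000, 50)
        assert np.allclose(g_lin(xi, fit), 1.0)

    def test_reference_point_is_fixed(self):
        fit = NonlinearityFit(1.0, 1e-7, 1e-12, 1.55, 7000.0)
        assert g_lin(7000.0, fit) == pytest.approx(1.0)

    def test_quadratic_toy_linearizes_mean_series(self):
        # forward-distort an exact linear ramp, correct it back: the
        # corrected series is linear with zero residual curvature
        x2 = 1e-7
        s = np.linspace(500.0, 30000.0, 40)
        measured = s - x2 * s**2
        fit = NonlinearityFit(0.0, x2, 0.0, 1.55, float(measured[20]))
        corrected = g_lin(measured, fit) * measured
        resid = corrected - np.polyval(np.polyfit(s, corrected, 1), s)
        assert np.max(np.abs(resid)) < 2e-4 * corrected.max()

    def test_out_of_range_error(self):
        fit = NonlinearityFit(0.0, 1e-3, 0.0, 1.55, 500.0)
        with pytest.raises(ValueError):
            g_lin(2000.0, fit)


class TestVarianceModel:
    def test_zero_signal_leaves_detector_floor(self):
        assert total_variance_model(0.0, 0.01, 1.55, 1.0, 8.8) == pytest.approx(17.6)

    def test_poisson_line_without_reference_noise(self):
        v = total_variance_model(1000.0, 0.0, 1.55, 1.0, 8.8)
        assert v == pytest.approx(1.55 * 1000.0 + 17.6)

    def test_matches_simulated_flat_series(self, det128, gain_ref_128):
        ref = gain_ref_128
        beam = BeamModel.flat(7050.0 / det128.g / T)
        sd2 = float(np.mean(det128.read_sigma**2 + det128.row_sigma**2))
        fac = float(np.mean(ref.phi**-2 + ref.sigma_ref**2 / ref.phi**4))
        for t in (0.4, 0.84, 1.6):
            vs, ms = [], []
            for i in range(8):
                ds = dark_subtract(
                    simulate_frame(det128, beam, t, (100, int(t * 100), i)),
                    simulate_dark(det128, t, (101, int(t * 100), i)),
                )
                f = apply_gain_reference(ds, ref)
                vs.append(np.var(f.data, ddof=1))
                ms.append(f.data.mean())
            model = total_variance_model(
                np.mean(ms), ref.k_ref, 1.55, 1.0, fac * (sd2 + 1.2 * t)
            )
            se3 = 3 * np.std(vs, ddof=1) / np.sqrt(len(vs))
            assert abs(np.mean(vs) - model) < max(se3, 0.02 * model)


class TestBFKernel:
    def test_identity_at_unity(self):
        k, sigma = bf_psf_from_beta(1.0)
        assert sigma == 0.0
        assert k.omega.max() == 1.0

    def test_reference_worked_example(self):
        # beta_BF = 0.995: sigma ~ 0.27 px, FWHM ~ 0.64 px, off-centre
        # mass ~ (1/beta - 1)/2 ~ 0.00251
        k, sigma = bf_psf_from_beta(0.995)
        assert sigma == pytest.approx(0.27, abs=0.01)
        assert sigma * FWHM == pytest.approx(0.64, abs=0.01)
        c = k.omega.shape[1] // 2
        assert 1.0 - k.omega[0, c] == pytest.approx((1 / 0.995 - 1) / 2, rel=0.01)

    def test_spike_migration_after_column_summation(self):
        # 30,000-count spike blurred by the reconstructed kernel loses ~75
        # counts from the central channel of the column-summed spectrum
        kern = bf_kernel_2d(0.995)
        img = np.zeros((33, 33))
        img[16, 16] = 30000.0
        spec = cconv2(img, kern.omega).sum(axis=0)
        migrated = 30000.0 - spec[16]
        assert round(migrated) == 75

    def test_round_trip_beta_from_kernel(self):
        # kernel -> Pearson sum -> 1/sum recovers beta within 2 % in sigma
        for beta in (0.99, 0.995, 0.999):
            k1, sigma = bf_psf_from_beta(beta)
            rho = rho_from_kernel(k1, radius=12)
            prof = rho.values[rho.center[0], :]
            beta_back = 1.0 / prof.sum()
            k2, sigma2 = bf_psf_from_beta(beta_back)
            assert sigma2 == pytest.approx(sigma, rel=0.02)

    def test_super_unity_warns_and_errors(self):
        with pytest.warns(RuntimeWarning):
            k, s = bf_psf_from_beta(1.05)
        assert s == 0.0
        with pytest.raises(ValueError):
            bf_psf_from_beta(1.2)
        with pytest.raises(ValueError):
            bf_psf_from_beta(0.0)


class TestPade:
    def test_interpolates_rational_function(self):
        x = np.linspace(100.0, 40000.0, 40)
        y = (1.0 + 2e-5 * x) / (1.0 + 3e-5 * x)
        a, b = fit_pade_45(x, y)
        from ccdnoise.linearity import _pade_eval

        assert np.max(np.abs(_pade_eval(a, b, x) - y)) < 1e-4


class TestBFCurve:
    def test_constant_curve(self):
        c = BFCurve.constant(7050.0)
        assert c.beta_bf(30000.0) == 1.0
        assert c.sigma_bf(30000.0) == 0.0

    def test_flat_detector_curve_is_unity(self, det128, gain_ref_128):
        ref = gain_ref_128
        beam = BeamModel.flat(7050.0 / det128.g / T)
        stacks, dds = [], []
        for z, t in enumerate((0.3, 0.6, 0.84, 1.3, 1.9)):
            group = []
            for r in range(6):
                ds = dark_subtract(
                    simulate_frame(det128, beam, t, (102, z, r)),
                    simulate_dark(det128, t, (103, z, r)),
                )
                group.append(apply_gain_reference(ds, ref))
            stacks.append(group)
            dds.append(
                apply_gain_reference(
                    dark_subtract(simulate_dark(det128, t, (104, z, 0)), simulate_dark(det128, t, (104, z, 1))),
                    ref,
                )
            )
        curve = estimate_bf_curve(stacks, ref, dds)
        assert curve.beta_bf(curve.ref_point) == pytest.approx(1.0)
        assert np.allclose(curve.beta, 1.0, atol=0.02)

    def test_injected_blur_recovered_against_forward_oracle(self):
        # detector with signal-dependent blur: the estimated nearest-
        # neighbour curve matches the curve predicted by propagating the
        # known base PSF through the same blur kernels (and decreases)
        S = np.linspace(0.0, 45000.0, 10)
        inj = BFCurve(S, np.clip(1.0 - 2.5e-6 * (S - 7050.0), 0.85, 1.05), 7050.0)
        det = DetectorModel.reference((128, 128), seed=33, bf_curve=inj)
        beam = BeamModel.flat(7050.0 / det.g / T)
        sigs = [simulate_frame(det, beam, T, (105, i)) for i in range(16)]
        darks = [simulate_dark(det, T, (106, i)) for i in range(16)]
        ref = build_gain_reference(sigs, darks, clean_cosmics=False)
        k, rho = estimate_kref_autocov(sigs, darks, ref.sigma_ref, clean_cosmics=False)
        ref.k_ref, ref.noise_rho = k, rho
        ts = (0.3, 0.84, 1.5, 2.2, 3.0)
        stacks, dds = [], []
        for z, t in enumerate(ts):
            group = []
            for r in range(8):
                ds = dark_subtract(
                    simulate_frame(det, beam, t, (107, z, r)), simulate_dark(det, t, (108, z, r))
                )
                group.append(apply_gain_reference(ds, ref))
            stacks.append(group)
            dds.append(
                apply_gain_reference(
                    dark_subtract(simulate_dark(det, t, (109, z, 0)), simulate_dark(det, t, (109, z, 1))),
                    ref,
                )
            )
        curve = estimate_bf_curve(stacks, ref, dds)

        # forward oracle: nearest-neighbour reciprocal sums of the base PSF
        # correlation convolved with each injected blur correlation,
        # normalized at the reference intensity
        base = rho_from_kernel(det.psf_d, radius=12).values

        def nn_inv(beta_inj):
            if beta_inj >= 1.0:
                vals = base
            else:
                blur = rho_from_kernel(bf_kernel_2d(beta_inj), radius=12).values
                vals = cconv2(base, blur)
                vals = vals / vals[12, 12]
            return 1.0 / vals[11:14, 11:14].sum()

        expect = np.array([nn_inv(float(inj.beta_bf(s))) for s in curve.counts])
        expect = expect / expect[np.argmin(np.abs(curve.counts - curve.ref_point))]
        assert np.max(np.abs(curve.beta - expect)) < 0.02
        assert curve.beta[-1] < 1.0  # decrease at high intensity


class TestBRE:
    def _series(self, det, decay_per_min, seed):
        # dense sub-threshold sampling pins the baseline line; the residual
        # slope then reflects genuine non-linearity, not extrapolation noise
        s_el0 = 7050.0 / det.g
        ts = [0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.8, 1.5, 2.2, 3.0, 4.0, 5.0]
        seq = []
        for t in ts:
            seq.extend([t, 1.0])
        seq = seq[:-1]
        out, elapsed = [], 0.0
        for j, t in enumerate(seq):
            beam = BeamModel.flat(s_el0 * np.exp(-decay_per_min * elapsed / 60.0))
            out.append(simulate_frame(det, beam, t, (seed, j)))
            elapsed += t + 1.0
        return out

    def test_constant_beam_linear_detector_passes(self):
        det = DetectorModel.reference((128, 128), seed=23)
        rep = bre_linearity_check(self._series(det, 0.0, 110), None)
        assert rep.passed

    def test_beam_decay_needs_bracket_correction(self):
        det = DetectorModel.reference((128, 128), seed=23)
        series = self._series(det, 0.05, 111)
        raw = bre_linearity_check(series, None, beam_correction=False)
        corr = bre_linearity_check(series, None, beam_correction=True)
        assert not raw.passed and raw.slope < 0
        assert corr.passed

    def test_saturation_needs_linearization(self):
        x2 = 5e-7
        det = DetectorModel.reference((128, 128), nonlin=(0.0, x2, 0.0), seed=23)
        series = self._series(det, 0.01, 112)
        bre_only = bre_linearity_check(series, None)
        assert not bre_only.passed and bre_only.slope < 0
        fit = NonlinearityFit(0.0, x2, 0.0, 1.55, 7302.0)
        full = bre_linearity_check(series, fit)
        assert full.passed

    def test_missing_brackets_error(self, det128):
        beam = BeamModel.flat(1000.0 / det128.g)
        frames = [simulate_frame(det128, beam, 1.0, (113, i)) for i in range(4)]
        with pytest.raises(ValueError):
            bre_linearity_check(frames, None)
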