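"""Calibration pipeline: artifact removal, noise decomposition, gain reference."""

import numpy as np
import pytest
from scipy.stats import norm

from ccdnoise.calibration import (
    apply_gain_reference,
    build_gain_reference,
    dark_subtract,
    estimate_kref_autocov,
    estimate_kref_difference,
    estimate_smoothed_gain,
    kref_theoretical,
    regress_read_thermal,
    remove_cosmic_rays,
    split_row_noise,
)
from ccdnoise.frames import Frame, quadrant_slices
from ccdnoise.simulate import (
    BeamModel,
    DetectorModel,
    inject_cosmic_rays,
    simulate_dark,
    simulate_frame,
)

T = 0.84


class TestRemoveCosmicRays:
    def test_single_spike_patched_with_neighbourhood(self, rng):
        data = rng.normal(100.0, 4.0, (64, 64))
        data[20, 30] = 100.0 + 15 * 4.0
        clean, mask = remove_cosmic_rays(Frame(data, 1.0))
        assert mask[20, 30]
        assert mask[19:22, 29:32].all()
        assert abs(clean.data[20, 30] - 100.0) < 1.0

    def test_false_positive_rate_on_clean_frame(self, rng):
        # expected false positives on 10^6 Gaussian pixels: 2 Phi(-5) 1e6 ~ 0.57
        data = rng.normal(0.0, 1.0, (1000, 1000))
        _, mask = remove_cosmic_rays(Frame(data, 1.0))
        n_seeds = int(mask.sum() / 9 + 0.5)  # each hit patches a 3x3 block
        assert n_seeds <= 6
        assert 2 * norm.cdf(-5) * 1e6 == pytest.approx(0.573, abs=0.01)

    def test_injected_rate_recovered_linear_in_time(self, det256):
        counts = []
        for t in (0.25, 0.5, 1.0):
            n = []
            for i in range(6):
                f = simulate_dark(det256, t, (70, i))
                f = inject_cosmic_rays(f, 36.5, (71, int(t * 100), i))
                _, mask = remove_cosmic_rays(f)
                n.append(mask.sum() / 9.0)
            counts.append(np.mean(n))
        ratios = np.array(counts) / counts[0]
        assert ratios == pytest.approx([1.0, 2.0, 4.0], rel=0.3)

    def test_contamination_error(self, rng):
        data = rng.normal(0, 1, (64, 64))
        idx = rng.choice(data.size, size=data.size // 50, replace=False)
        data.ravel()[idx] = 1e4
        with pytest.raises(ValueError):
            remove_cosmic_rays(Frame(data, 1.0))


class TestDarkSubtract:
    def test_identical_frames_cancel(self, det128):
        d = simulate_dark(det128, 1.0, 72)
        out = dark_subtract(d, d)
        assert np.allclose(out.data, 0.0)

    def test_variance_doubles_for_dark_pair(self, det128):
        out = [
            dark_subtract(simulate_dark(det128, 0.0, (73, i, 0)), simulate_dark(det128, 0.0, (73, i, 1)))
            for i in range(10)
        ]
        var = np.mean([f.data.var() for f in out])
        expect = 2 * float(np.mean(det128.read_sigma**2 + det128.row_sigma**2))
        assert var == pytest.approx(expect, rel=0.05)
        assert np.mean([f.data.mean() for f in out]) == pytest.approx(0.0, abs=0.2)

    def test_signal_pair_mean_and_variance(self, det128):
        beam = BeamModel.flat(7050.0 / det128.g / T)
        outs = [
            dark_subtract(
                simulate_frame(det128, beam, T, (74, i)), simulate_dark(det128, T, (75, i))
            )
            for i in range(10)
        ]
        assert np.mean([o.data.mean() for o in outs]) == pytest.approx(7050.0, rel=0.01)
        beta_conv = float((det128.psf_d.omega**2).sum())
        sigma_d2 = float(np.mean(det128.read_sigma**2 + det128.row_sigma**2)) + 1.2 * T
        qe = float((det128.gain_map**2).mean())
        expect = beta_conv * det128.g * 7050.0 * qe + 7050.0**2 * det128.gain_map.var() + 2 * sigma_d2
        var = np.mean([o.data.var() for o in outs])
        assert var == pytest.approx(expect, rel=0.05)

    def test_mismatch_errors(self, det128):
        d = simulate_dark(det128, 1.0, 76)
        with pytest.raises(ValueError):
            dark_subtract(d, simulate_dark(det128, 2.0, 77))


class TestSplitRowNoise:
    def test_integer_offsets_recovered_exactly(self, rng):
        data = rng.normal(0.0, 0.3, (6, 200))
        offsets = np.array([-1.0, 0.0, 2.0, 1.0, 0.0, -2.0])
        frame = Frame(data + offsets[:, None], 1.0)
        resid, rows = split_row_noise(frame)
        # quadrants split the 6 rows into 3+3; offsets constant per row
        assert np.allclose(rows.data[:, 0], offsets)
        assert np.allclose(resid.data + rows.data, frame.data)

    def test_decomposition_bit_exact(self, det128):
        f = dark_subtract(simulate_dark(det128, 1.0, 78), simulate_dark(det128, 1.0, 79))
        resid, rows = split_row_noise(f)
        assert np.array_equal(resid.data + rows.data, f.data)

    def test_misrounding_probability_is_negligible_at_reference_width(self):
        # row-mean SD of 0.126 counts: one-sided tail beyond 0.5
        assert norm.sf(0.5 / 0.126) == pytest.approx(3.6e-5, rel=0.15)


class TestRegression:
    @pytest.fixture(scope="class")
    def dark_series(self, det256):
        frames = []
        for j, t in enumerate([0.0, 0.5, 1.0, 2.0, 3.0, 4.75]):
            for r in range(3):
                frames.append(
                    dark_subtract(
                        simulate_dark(det256, t, (80, j, r, 0)),
                        simulate_dark(det256, t, (80, j, r, 1)),
                    )
                )
        return frames

    def test_read_and_thermal_recovery(self, dark_series):
        nb = regress_read_thermal(dark_series, clean_cosmics=False)
        assert np.sqrt(nb.read_var) == pytest.approx([4.0] * 4, rel=0.03)
        assert nb.thermal_rate == pytest.approx([1.2] * 4, rel=0.15)
        assert np.sqrt(nb.row_var) == pytest.approx([0.6] * 4, rel=0.1)

    def test_zero_dark_current_slope_consistent_with_zero(self):
        det = DetectorModel.reference((128, 128), seed=13, dark_rate=0.0)
        frames = [
            dark_subtract(simulate_dark(det, t, (81, j, 0)), simulate_dark(det, t, (81, j, 1)))
            for j, t in enumerate([0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        ]
        nb = regress_read_thermal(frames, clean_cosmics=False)
        for q in range(4):
            lo, hi = nb.thermal_rate_ci[q]
            assert lo <= 0.05  # slope indistinguishable from zero

    def test_gain_reference_scaling(self, dark_series, gain_ref_256):
        ref = gain_ref_256
        scaled = [f.copy_with(f.data / ref.map) for f in dark_series]
        nb_raw = regress_read_thermal(dark_series, clean_cosmics=False)
        nb_fit = regress_read_thermal(scaled, clean_cosmics=False)  # fitted, unscaled
        nb_corr = regress_read_thermal(scaled, ref=ref, clean_cosmics=False)
        fac = ref.phi**-2 + ref.sigma_ref**2 / ref.phi**4
        # raw fitted values of the normalized stack carry the variance factor
        assert nb_fit.read_var == pytest.approx(nb_raw.read_var * fac, rel=0.02)
        # passing the reference divides it back out
        assert nb_corr.read_var == pytest.approx(nb_raw.read_var, rel=0.02)

    def test_too_few_exposures(self, det128):
        frames = [
            dark_subtract(simulate_dark(det128, t, (82, j, 0)), simulate_dark(det128, t, (82, j, 1)))
            for j, t in enumerate([1.0, 2.0])
        ]
        with pytest.raises(ValueError):
            regress_read_thermal(frames)


class TestGainReference:
    def test_map_properties(self, gain_ref_256, det256):
        ref = gain_ref_256
        assert ref.map.mean() == pytest.approx(1.0, abs=1e-9)
        assert ref.w == 30
        assert ref.s_ref_c == pytest.approx(7050.0, rel=0.01)
        # map correlates strongly with the true fixed pattern
        r = np.corrcoef(ref.map.ravel(), det256.gain_map.ravel())[0, 1]
        assert r > 0.99

    def test_single_noiseless_pair_recovers_gain_map(self):
        det = DetectorModel.reference(
            (64, 64), seed=15, read_sigma=0.0, row_sigma=0.0, dark_rate=0.0, psf_fwhm=1e-3
        )
        s_el = np.full(det.shape, 1.0)
        sig = Frame(det.g * det.gain_map * 1e6, T)
        dark = Frame(np.zeros(det.shape), T)
        ref = build_gain_reference([sig], [dark], clean_cosmics=False)
        assert np.allclose(ref.map, det.gain_map, atol=1e-9)

    def test_kref_matches_closed_form(self, gain_ref_256, det256):
        ref = gain_ref_256
        beta_conv = float((det256.psf_d.omega**2).sum())
        sigma_d2 = float(np.mean(det256.read_sigma**2 + det256.row_sigma**2)) + 1.2 * T
        k_th = kref_theoretical(ref.s_ref_c, det256.g, beta_conv, sigma_d2, ref.w)
        assert ref.k_ref == pytest.approx(k_th, rel=0.05)

    def test_kref_estimators_agree(self, det128):
        # difference-image route vs autocovariance route, < 1 % apart
        beam = BeamModel.flat(7050.0 / det128.g / T)
        w = 16
        sA = [simulate_frame(det128, beam, T, (83, i)) for i in range(w)]
        dA = [simulate_dark(det128, T, (84, i)) for i in range(w)]
        sB = [simulate_frame(det128, beam, T, (85, i)) for i in range(w)]
        dB = [simulate_dark(det128, T, (86, i)) for i in range(w)]
        refA = build_gain_reference(sA, dA, clean_cosmics=False)
        refB = build_gain_reference(sB, dB, clean_cosmics=False)
        k_diff = estimate_kref_difference(refA, refB)
        k_ac, _ = estimate_kref_autocov(sA + sB, dA + dB, refA.sigma_ref, clean_cosmics=False)
        # the autocov route saw w = 32 frames, the difference route compares
        # two w = 16 references, so k scales by sqrt(2); agreement at the
        # per-cent level (desk-scale sampling noise)
        assert k_diff == pytest.approx(k_ac * np.sqrt(2.0), rel=0.02)

    def test_kref_theoretical_limits(self):
        # sigma_d = 0, w = 1: k^2 = beta g / S_ref,c  (pure Poisson limit)
        k = kref_theoretical(7050.0, 14.0, 0.11, 0.0, 1)
        assert k**2 == pytest.approx(14.0 * 0.11 / 7050.0)
        # doubling w at fixed S halves k^2
        k2 = kref_theoretical(7050.0, 14.0, 0.11, 8.8, 2)
        k1 = kref_theoretical(7050.0, 14.0, 0.11, 8.8, 1)
        assert k2**2 == pytest.approx(k1**2 / 2.0)
        # inversion back to the smoothed gain from k and the detector noise
        s, bg, sd2, w = 7050.0, 1.55, 8.8, 30
        k = kref_theoretical(s, bg, 1.0, sd2, w)
        assert (k**2 * w * s**2 - 2 * sd2) / s == pytest.approx(bg, rel=1e-9)

    def test_identical_references_give_zero(self, gain_ref_256):
        assert estimate_kref_difference(gain_ref_256, gain_ref_256) == 0.0


class TestApplyGainReference:
    def test_unit_map_is_identity(self, det128):
        ref = build_gain_reference(
            [Frame(np.full(det128.shape, 5000.0), T)],
            [Frame(np.zeros(det128.shape), T)],
            clean_cosmics=False,
        )
        f = simulate_dark(det128, 1.0, 87)
        out = apply_gain_reference(f, ref)
        assert np.allclose(out.data, f.data)

    def test_fixed_pattern_removed(self, det256, flat_beam_256, gain_ref_256):
        # gain-normalized flats lose the S^2 fixed-pattern variance term
        raw, norm_ = [], []
        for i in range(6):
            ds = dark_subtract(
                simulate_frame(det256, flat_beam_256, T, (88, i)),
                simulate_dark(det256, T, (89, i)),
            )
            raw.append(ds.data.var())
            norm_.append(apply_gain_reference(ds, gain_ref_256).data.var())
        fp = 7050.0**2 * det256.gain_map.var()
        assert np.mean(raw) - np.mean(norm_) == pytest.approx(fp, rel=0.1)

    def test_dark_noise_inflation(self, det256, gain_ref_256):
        ref = gain_ref_256
        outs, ins = [], []
        for i in range(12):
            d = dark_subtract(simulate_dark(det256, 0.0, (90, i, 0)), simulate_dark(det256, 0.0, (90, i, 1)))
            ins.append(d.data.std())
            outs.append(apply_gain_reference(d, ref).data.std())
        fac = np.sqrt(np.mean(ref.phi**-2 + ref.sigma_ref**2 / ref.phi**4))
        assert np.mean(outs) / np.mean(ins) == pytest.approx(fac, rel=0.005)


class TestSmoothedGain:
    def test_recovery_within_two_percent(self, det256, flat_beam_256, gain_ref_256):
        ref = gain_ref_256
        flats = []
        for i in range(10):
            ds = dark_subtract(
                simulate_frame(det256, flat_beam_256, T, (91, i)),
                simulate_dark(det256, T, (92, i)),
            )
            flats.append(apply_gain_reference(ds, ref))
        dd = apply_gain_reference(
            dark_subtract(simulate_dark(det256, T, (93, 0)), simulate_dark(det256, T, (93, 1))),
            ref,
        )
        res = estimate_smoothed_gain(flats, ref, dd)
        beta_conv = float((det256.psf_d.omega**2).sum())
        assert res.beta_g == pytest.approx(det256.g * beta_conv, rel=0.02)

    def test_delta_psf_detector_yields_raw_gain(self):
        det = DetectorModel.reference((128, 128), seed=17, psf_fwhm=1e-3, g=1.6)
        beam = BeamModel.flat(7050.0 / det.g / T)
        sigs = [simulate_frame(det, beam, T, (94, i)) for i in range(16)]
        darks = [simulate_dark(det, T, (95, i)) for i in range(16)]
        ref = build_gain_reference(sigs, darks, clean_cosmics=False)
        k, rho = estimate_kref_autocov(sigs, darks, ref.sigma_ref, clean_cosmics=False)
        ref.k_ref, ref.noise_rho = k, rho
        flats = []
        for i in range(8):
            ds = dark_subtract(simulate_frame(det, beam, T, (96, i)), simulate_dark(det, T, (97, i)))
            flats.append(apply_gain_reference(ds, ref))
        dd = apply_gain_reference(
            dark_subtract(simulate_dark(det, T, (98, 0)), simulate_dark(det, T, (98, 1))), ref
        )
        res = estimate_smoothed_gain(flats, ref, dd)
        assert res.beta_g == pytest.approx(1.6, rel=0.02)

    def test_missing_noise_field_raises(self, det128, refstack128):
        sigs, darks = refstack128
        ref = build_gain_reference(sigs, darks, clean_cosmics=False)
        dd = dark_subtract(simulate_dark(det128, T, (99, 0)), simulate_dark(det128, T, (99, 1)))
        with pytest.raises(ValueError):
            estimate_smoothed_gain(dd, ref, dd)
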