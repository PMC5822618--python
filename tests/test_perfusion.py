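import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfquant.perfusion import (
    ConcentrationCurve,
    FermiBounds,
    FermiParams,
    compute_mpr,
    fermi_irf,
    first_pass_window,
    fit_fermi,
    global_perfusion,
    model_tissue_curve,
    pixelwise_mbf,
    resample_uniform,
)
from perfquant.synthetic import gen_aif, gen_tissue_curve

FINE_T = np.arange(0.0, 49.01, 0.02)


def make_curves(mbf, dt=0.5, shape=None):
    """Noiseless AIF + tissue curve pair on a uniform grid."""
    aif = gen_aif(times=FINE_T)
    ct = gen_tissue_curve(aif, mbf, shape)
    return resample_uniform(aif, dt), resample_uniform(ct, dt)


class TestFermiIrf:
    def test_zero_decay_gives_constant_half_amplitude(self):
        p = FermiParams(amplitude_f=2.0, decay_k=0.0, width_w=10.0,
                        delay_td=1.0)
        t = np.array([1.0, 5.0, 50.0])
        np.testing.assert_allclose(fermi_irf(t, p), 1.0)

    def test_large_width_plateau_approaches_amplitude(self):
        p = FermiParams(amplitude_f=2.0, decay_k=1.0, width_w=25.0,
                        delay_td=0.5)
        assert p.mbf == pytest.approx(2.0, rel=1e-9)

    def test_zero_before_delay(self):
        p = FermiParams(amplitude_f=1.0, decay_k=0.5, width_w=4.0,
                        delay_td=2.0)
        np.testing.assert_array_equal(fermi_irf(np.array([0.0, 1.9]), p), 0.0)

    def test_hand_evaluated_formula(self):
        p = FermiParams(amplitude_f=2.0, decay_k=0.5, width_w=4.0,
                        delay_td=1.0)
        r1 = 2.0 / (1.0 + np.exp(0.5 * (1.0 - 1.0 - 4.0)))
        r21 = 2.0 / (1.0 + np.exp(0.5 * (21.0 - 1.0 - 4.0)))
        assert fermi_irf(1.0, p) == pytest.approx(r1, rel=1e-12)
        assert fermi_irf(21.0, p) == pytest.approx(r21, rel=1e-12)
        assert fermi_irf(1.0, p) / fermi_irf(21.0, p) == pytest.approx(
            r1 / r21, rel=1e-12)

    def test_nonincreasing_after_delay(self):
        p = FermiParams(amplitude_f=3.0, decay_k=0.4, width_w=6.0,
                        delay_td=1.0)
        t = np.linspace(1.0, 40.0, 200)
        assert np.all(np.diff(fermi_irf(t, p)) <= 1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FermiParams(amplitude_f=-1.0, decay_k=0.1, width_w=1.0,
                        delay_td=0.0)
        with pytest.raises(ValueError):
            FermiParams(amplitude_f=1.0, decay_k=0.1, width_w=1.0,
                        delay_td=9.0)


class TestFermiIrfProperties:
    @given(f=st.floats(0.05, 8.0), k=st.floats(0.0, 5.0),
           w=st.floats(0.0, 30.0), td=st.floats(0.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_nonnegative(self, f, k, w, td):
        p = FermiParams(amplitude_f=f, decay_k=k, width_w=w, delay_td=td)
        t = np.linspace(0.0, 60.0, 121)
        r = fermi_irf(t, p)
        assert np.all(r >= 0.0)
        assert np.all(r <= f + 1e-12)
        assert 0.0 < p.mbf <= f + 1e-12

    @given(st.floats(0.3, 5.0), st.floats(0.3, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_mpr_homogeneity(self, stress, rest):
        assert compute_mpr(stress, rest) == pytest.approx(
            2.0 * stress / (2.0 * rest), rel=1e-12)


class TestModelTissueCurve:
    def test_impulse_identity(self):
        """A discrete impulse of unit area at t=0 (trapezoid boundary weight
        1/2 => value 2/dt) reproduces R/60 on the grid."""
        dt = 0.5
        t = dt * np.arange(60)
        vals = np.zeros_like(t)
        vals[0] = 2.0 / dt
        aif = ConcentrationCurve(times=t, values=vals, kind="aif")
        p = FermiParams(amplitude_f=2.0, decay_k=0.3, width_w=8.0,
                        delay_td=1.0)
        ct = model_tissue_curve(aif, p)
        expected = fermi_irf(t, p) / 60.0
        np.testing.assert_allclose(ct.values[1:], expected[1:], rtol=1e-12)

    def test_zero_aif_gives_zero_tissue(self):
        t = 0.5 * np.arange(40)
        aif = ConcentrationCurve(times=t, values=np.zeros_like(t), kind="aif")
        p = FermiParams.from_mbf(2.0)
        np.testing.assert_array_equal(model_tissue_curve(aif, p).values, 0.0)

    def test_matches_double_loop_oracle(self):
        """Independent O(n^2) trapezoidal convolution, written as explicit
        loops over the integration variable."""
        aif = resample_uniform(gen_aif(times=FINE_T), 0.5)
        p = FermiParams(amplitude_f=1.7, decay_k=0.25, width_w=7.0,
                        delay_td=1.5)
        got = model_tissue_curve(aif, p).values
        dt = 0.5
        n = len(aif)
        expected = np.zeros(n)
        for i in range(n):
            acc = 0.0
            for j in range(i + 1):
                w = 0.5 if j in (0, i) else 1.0
                acc += w * aif.values[j] * fermi_irf((i - j) * dt, p)
            expected[i] = acc * dt / 60.0
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_linear_in_amplitude(self):
        aif = resample_uniform(gen_aif(times=FINE_T), 0.5)
        p1 = FermiParams(amplitude_f=1.0, decay_k=0.3, width_w=8.0,
                         delay_td=1.0)
        p2 = FermiParams(amplitude_f=2.0, decay_k=0.3, width_w=8.0,
                         delay_td=1.0)
        np.testing.assert_allclose(2.0 * model_tissue_curve(aif, p1).values,
                                   model_tissue_curve(aif, p2).values,
                                   rtol=1e-12)

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.5, 1.5, 2.0])
        aif = ConcentrationCurve(times=t, values=np.ones(4), kind="aif")
        with pytest.raises(ValueError, match="uniform"):
            model_tissue_curve(aif, FermiParams.from_mbf(1.0))


class TestFitFermi:
    def test_noiseless_recovery_within_1pct(self):
        aif, ct = make_curves(2.0)
        p, d = fit_fermi(aif, ct, seed=0)
        assert d.converged
        assert p.mbf == pytest.approx(2.0, rel=0.01)

    def test_zero_tissue_flagged_degenerate(self):
        aif, ct = make_curves(1.0)
        zero = ConcentrationCurve(times=ct.times,
                                  values=np.zeros_like(ct.values),
                                  kind="tissue")
        p, d = fit_fermi(aif, zero, seed=0)
        assert "degenerate" in d.flags

    def test_monotone_recovery_sweep(self):
        grid = [0.5, 1.0, 2.0, 4.0]
        recovered = []
        for mbf in grid:
            aif, ct = make_curves(mbf)
            p, _ = fit_fermi(aif, ct, seed=0)
            recovered.append(p.mbf)
            assert p.mbf == pytest.approx(mbf, rel=0.02)
        assert np.all(np.diff(recovered) > 0)

    def test_too_few_samples(self):
        t = 0.5 * np.arange(5)
        c = ConcentrationCurve(times=t, values=np.ones(5))
        a = ConcentrationCurve(times=t, values=np.ones(5), kind="aif")
        with pytest.raises(ValueError, match="10 samples"):
            fit_fermi(a, c)

    def test_mismatched_grids(self):
        aif, ct = make_curves(1.0)
        other = ConcentrationCurve(times=ct.times + 0.1, values=ct.values)
        with pytest.raises(ValueError, match="time grid"):
            fit_fermi(aif, other)


class TestParameterRecoveryProperties:
    def test_noiseless_recovery_under_2pct_across_range(self, rng):
        """200 noiseless curves spanning the physiologic flow range."""
        aif = resample_uniform(gen_aif(times=FINE_T), 0.5)
        mbfs = rng.uniform(0.5, 4.5, 200)
        worst = 0.0
        for mbf in mbfs:
            shape = {"decay_k": rng.uniform(0.15, 0.5),
                     "width_w": rng.uniform(5.0, 12.0),
                     "delay_td": rng.uniform(0.2, 2.5)}
            ct = gen_tissue_curve(aif, float(mbf), shape)
            p, _ = fit_fermi(aif, ct, seed=0, n_starts=3)
            worst = max(worst, abs(p.mbf - mbf) / mbf)
        assert worst < 0.02

    def test_noisy_recovery_median_under_10pct(self, rng):
        """Gaussian noise at curve SNR 20 (sigma = peak/20)."""
        aif = resample_uniform(gen_aif(times=FINE_T), 0.5)
        errs = []
        for mbf in (0.5, 1.0, 2.0, 4.0):
            ct = gen_tissue_curve(aif, mbf)
            sigma = ct.values.max() / 20.0
            for _ in range(25):
                noisy = ConcentrationCurve(
                    times=ct.times,
                    values=ct.values + rng.normal(0, sigma, ct.values.shape),
                    kind="tissue")
                p, _ = fit_fermi(aif, noisy, seed=0, n_starts=3)
                errs.append(abs(p.mbf - mbf) / mbf)
        assert np.median(errs) < 0.10

    def test_mpr_scale_invariance(self):
        """Scaling all concentrations by a common factor leaves MPR
        unchanged within 1%."""
        aif, rest_ct = make_curves(1.2)
        _, stress_ct = make_curves(3.1)

        def mpr_from(scale):
            sa = ConcentrationCurve(times=aif.times, values=scale * aif.values,
                                    kind="aif")
            sr = ConcentrationCurve(times=rest_ct.times,
                                    values=scale * rest_ct.values)
            ss = ConcentrationCurve(times=stress_ct.times,
                                    values=scale * stress_ct.values)
            pr, _ = fit_fermi(sa, sr, seed=0)
            ps, _ = fit_fermi(sa, ss, seed=0)
            return compute_mpr(ps.mbf, pr.mbf)

        assert mpr_from(2.5) == pytest.approx(mpr_from(1.0), rel=0.01)


class TestGridSearchOracle:
    def test_continuous_fit_beats_coarse_grid(self, rng):
        """On 3 fixed seeded curves the continuous optimum's residual is no
        worse than an exhaustive coarse grid search over the constraint
        box, both evaluated through the public forward model."""
        aif = resample_uniform(gen_aif(times=FINE_T), 0.5)
        b = FermiBounds()
        amps = np.linspace(0.1, 6.0, 8)
        ks = np.linspace(0.05, 2.0, 5)
        ws = np.linspace(1.0, 20.0, 5)
        tds = np.linspace(0.0, 3.0, 4)
        for i in range(3):
            mbf = [0.8, 1.9, 3.4][i]
            ct = gen_tissue_curve(aif, mbf)
            noisy = ConcentrationCurve(
                times=ct.times,
                values=ct.values + rng.normal(0, 0.01, ct.values.shape),
                kind="tissue")

            def objective(p):
                return float(np.linalg.norm(
                    model_tissue_curve(aif, p).values - noisy.values))

            grid_best = min(
                objective(FermiParams(amplitude_f=a, decay_k=k, width_w=w,
                                      delay_td=td))
                for a in amps for k in ks for w in ws for td in tds)
            p_fit, _ = fit_fermi(aif, noisy, bounds=b, window=False,
                                 oversample=1, seed=0)
            assert objective(p_fit) <= grid_best + 1e-9


class TestWindow:
    def test_window_starts_at_arrival(self):
        aif = resample_uniform(gen_aif(t_arrival=6.0, times=FINE_T), 0.5)
        start, stop = first_pass_window(aif)
        assert aif.times[start] >= 6.0
        assert aif.times[start] <= 6.0 + 3.0
        assert stop > start

    def test_flat_aif_rejected(self):
        t = 0.5 * np.arange(30)
        aif = ConcentrationCurve(times=t, values=np.zeros_like(t), kind="aif")
        with pytest.raises(ValueError, match="peak"):
            first_pass_window(aif)


class TestPixelwiseAndGlobal:
    def test_single_pixel_equals_fit_fermi(self):
        aif, ct = make_curves(2.0)
        stack = ct.values[:, None, None]
        mask = np.ones((1, 1), dtype=bool)
        mbf_map, diags = pixelwise_mbf(stack, ct.times, aif, mask,
                                       shape_from_roi=False, seed=0)
        p, _ = fit_fermi(aif, ct, seed=0)
        assert mbf_map[0, 0] == pytest.approx(p.mbf, rel=1e-9)

    def test_two_region_phantom_at_snr20(self):
        from perfquant.config import StudyConfig
        from perfquant.pipeline import quantify_series
        from perfquant.synthetic import gen_dynamic_series

        truth = np.ones((8, 8))
        truth[:, 4:] = 3.0
        series = gen_dynamic_series(truth, snr=20.0, seed=11)
        res = quantify_series(series, StudyConfig(), seed=0)
        m = res["mbf_map"]
        assert np.nanmean(m[:, :4]) == pytest.approx(1.0, rel=0.05)
        assert np.nanmean(m[:, 4:]) == pytest.approx(3.0, rel=0.05)

    def test_uniform_phantom_cov_within_noise_bound(self):
        """Map coefficient of variation stays below a Monte-Carlo noise
        bound (3x the median per-pixel error at this SNR)."""
        from perfquant.config import StudyConfig
        from perfquant.pipeline import quantify_series
        from perfquant.synthetic import gen_dynamic_series

        series = gen_dynamic_series(np.full((8, 8), 2.0), snr=20.0, seed=13)
        res = quantify_series(series, StudyConfig(), seed=0)
        m = res["mbf_map"][np.isfinite(res["mbf_map"])]
        cov = m.std() / m.mean()
        median_err = np.median(np.abs(m - 2.0) / 2.0)
        assert cov < 3.0 * max(median_err, 0.02)

    def test_empty_mask_rejected(self):
        aif, ct = make_curves(1.0)
        with pytest.raises(ValueError, match="mask"):
            pixelwise_mbf(ct.values[:, None, None], ct.times, aif,
                          np.zeros((1, 1), dtype=bool))

    def test_global_perfusion_mean(self):
        assert global_perfusion(np.array([1.0, 2.0, 3.0])) == 2.0

    def test_global_perfusion_excludes_invalid(self):
        assert global_perfusion(np.array([1.0, 2.0, np.nan])) == 1.5

    def test_global_perfusion_no_valid(self):
        with pytest.raises(ValueError):
            global_perfusion(np.array([np.nan, np.nan]))


class TestMpr:
    def test_unity(self):
        assert compute_mpr(2.0, 2.0) == 1.0

    def test_ratio(self):
        assert compute_mpr(3.0, 1.0) == 3.0

    def test_zero_rest_rejected(self):
        with pytest.raises(ValueError):
            compute_mpr(3.0, 0.0)

    def test_full_chain_subject_recovery(self):
        from perfquant.config import StudyConfig
        from perfquant.pipeline import simulate_subject_exam

        res = simulate_subject_exam(1.0, 2.8, StudyConfig(), seed=1, grid=6,
                                    n_slices=2)
        assert res.mpr == pytest.approx(2.8, rel=0.05)
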