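"""Tests of the center-size and surround-amplitude estimators and the mean
receptive field."""

import numpy as np
import pytest
from scipy import stats

from rgcadapt.ln_models import (
    CROP_SIZE,
    N_LAGS,
    DoGLNParams,
    GaussianSpatialFilter,
    SpatiotemporalRF,
    TemporalFilter,
    build_spatiotemporal_rf,
    render_spatial,
)
from rgcadapt.receptive_fields import (
    center_size_dog,
    clip_small,
    find_surround_frame,
    fit_dog_posthoc,
    mean_receptive_field,
    posthoc_center_size,
    posthoc_surround_strength,
    smoothed_surround_amplitude,
    surround_amplitude,
    threshold_center_size,
)


def dog_params(center_cov, surround_cov=None, a1=1.0, a2=0.2, mean=None):
    mean = np.array([7.0, 7.0]) if mean is None else np.asarray(mean, dtype=float)
    surround_cov = 4 * np.asarray(center_cov) if surround_cov is None else surround_cov
    t = np.zeros(N_LAGS)
    t[3] = 0.9
    t[10] = -np.sqrt(1 - 0.81)
    # surround temporal profile overlaps the center peak so the DoG slice
    # at the max frame carries a genuine antagonistic ring
    t2 = np.zeros(N_LAGS)
    t2[3] = 0.8
    t2[12] = 0.6
    return DoGLNParams(
        g1=GaussianSpatialFilter(a1, mean, center_cov),
        g2=GaussianSpatialFilter(a2, mean.copy(), surround_cov),
        t1=TemporalFilter(t),
        t2=TemporalFilter(t2),
    )


class TestCenterSizeDog:
    def test_identity_covariance_gives_4pi(self):
        p = dog_params(np.eye(2))
        assert center_size_dog(p) == pytest.approx(4 * np.pi)

    def test_anisotropic_matches_pixel_count_of_2sd_ellipse(self):
        cov = np.diag([4.0, 1.0])
        p = dog_params(cov)
        s = center_size_dog(p)
        assert s == pytest.approx(8 * np.pi, rel=1e-12)
        # pixel-count oracle on a fine grid: area where d' cov^-1 d <= 4
        xs = np.linspace(-10, 10, 2001)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        q = X**2 / 4 + Y**2
        area = np.count_nonzero(q <= 4.0) * (xs[1] - xs[0]) ** 2
        assert s == pytest.approx(area, rel=0.01)

    def test_homogeneous_in_covariance_scale(self):
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        c = 3.1
        assert center_size_dog(dog_params(c * cov)) == pytest.approx(
            c * center_size_dog(dog_params(cov))
        )


class TestSurroundFrame:
    def test_pure_center_rank_one_has_no_surround(self):
        p = dog_params(np.eye(2), a2=0.0)
        rf = build_spatiotemporal_rf(p)
        _, s_frame = find_surround_frame(rf, "ON", center_pixel=(7, 7))
        assert s_frame is None
        assert surround_amplitude(rf, "ON", center_pixel=(7, 7)) == 0.0

    def test_constructed_extremum_found_and_matches_brute_force(self):
        values = np.zeros((N_LAGS, CROP_SIZE, CROP_SIZE))
        values[:, 7, 7] = 1.0  # ON center throughout
        values[5, 7, 7] = 2.0  # max frame at 5
        values[8, 2, 3] = -0.7  # opposite-polarity extremum at max_frame + 3
        values[10, 4, 4] = -0.4
        rf = SpatiotemporalRF(values)
        max_frame, s_frame = find_surround_frame(rf, "ON", window=6, center_pixel=(7, 7))
        assert (max_frame, s_frame) == (5, 8)
        # brute-force window oracle
        best, mag = None, 0.0
        for f in range(max(0, 5 - 6), min(N_LAGS, 5 + 7)):
            if values[f, 7, 7] <= 0:
                continue
            m = (-values[f]).max()
            if m > mag:
                best, mag = f, m
        assert best == s_frame

    def test_flipped_center_sign_excludes_frame(self):
        values = np.zeros((N_LAGS, CROP_SIZE, CROP_SIZE))
        values[:, 7, 7] = 1.0
        values[5, 7, 7] = 2.0
        values[7, 7, 7] = -0.5  # center flips sign at max_frame + 2
        values[7, 1, 1] = -5.0  # global opposite extremum lives there
        values[9, 2, 2] = -0.3
        rf = SpatiotemporalRF(values)
        _, s_frame = find_surround_frame(rf, "ON", window=6, center_pixel=(7, 7))
        assert s_frame == 9

    def test_surround_amplitude_matches_construction_depth(self):
        p = dog_params(np.eye(2), a2=0.35, mean=np.array([7.0, 7.0]))
        rf = build_spatiotemporal_rf(p)
        got = surround_amplitude(rf, "ON", center_pixel=(7, 7))
        # oracle: normalize by center pixel at max frame, scan the window
        trace = rf.values[:, 7, 7]
        mf = int(np.argmax(trace))
        norm = rf.values / abs(trace[mf])
        best = 0.0
        for f in range(max(0, mf - 6), min(N_LAGS, mf + 7)):
            if norm[f, 7, 7] > 0:
                best = max(best, (-norm[f]).max())
        assert got == pytest.approx(best, abs=1e-6)

    def test_clip_small_summary_convention(self):
        assert clip_small(5e-5) == 0.0
        assert clip_small(2e-3) == 2e-3


class TestMeanReceptiveField:
    def test_single_filter_identity(self):
        p = dog_params(np.eye(2), a2=0.3)
        rf = build_spatiotemporal_rf(p)
        out = mean_receptive_field([rf], ["ON"], [(7.0, 7.0)])
        trace = rf.values[:, 7, 7]
        scaled = rf.values / trace.max()
        _, s_frame = find_surround_frame(SpatiotemporalRF(scaled), "ON", center_pixel=(7, 7))
        np.testing.assert_allclose(out, scaled[s_frame], atol=1e-12)

    def test_idempotent_under_duplication(self):
        p = dog_params(np.eye(2), a2=0.3)
        rf = build_spatiotemporal_rf(p)
        one = mean_receptive_field([rf], ["ON"], [(7.0, 7.0)])
        two = mean_receptive_field([rf, rf], ["ON", "ON"], [(7.0, 7.0), (7.0, 7.0)])
        np.testing.assert_allclose(one, two)

    def test_offset_filter_shifted_with_zero_fill(self):
        p_centered = dog_params(np.eye(2), a2=0.0)
        p_shifted = dog_params(np.eye(2), a2=0.0, mean=np.array([7.0, 9.0]))
        rf_c = build_spatiotemporal_rf(p_centered)
        rf_s = build_spatiotemporal_rf(p_shifted)
        out = mean_receptive_field(
            [rf_c, rf_s], ["ON", "ON"], [(7.0, 7.0), (7.0, 9.0)]
        )
        oracle = mean_receptive_field([rf_c], ["ON"], [(7.0, 7.0)])
        # the shifted copy re-centers onto the same image, except two vacated
        # columns on the right that average with zero
        np.testing.assert_allclose(out[:, :13], oracle[:, :13], atol=1e-10)
        np.testing.assert_allclose(out[:, 13:], oracle[:, 13:] / 2, atol=1e-10)


class TestPosthocDoG:
    def test_noiseless_recovery_within_two_percent(self):
        cov_c = np.diag([2.2, 1.7])
        cov_s = np.diag([8.0, 7.0])
        mu = np.array([7.4, 6.8])
        img = render_spatial(
            GaussianSpatialFilter(1.0, mu, cov_c)
        ) - render_spatial(GaussianSpatialFilter(0.25, mu, cov_s))
        fit = fit_dog_posthoc(img)
        assert fit.a_c == pytest.approx(1.0, rel=0.02)
        assert fit.a_s == pytest.approx(0.25, rel=0.02)
        np.testing.assert_allclose(np.diag(fit.cov_c), np.diag(cov_c), rtol=0.02)
        np.testing.assert_allclose(np.diag(fit.cov_s), np.diag(cov_s), rtol=0.02)

    def test_single_gaussian_fits_negligible_surround(self):
        img = render_spatial(GaussianSpatialFilter(1.0, np.array([7.0, 7.0]), np.diag([2.0, 2.0])))
        fit = fit_dog_posthoc(img)
        assert abs(fit.a_s) < 0.02 * abs(fit.a_c)

    def test_fit_mse_not_worse_than_initialization(self):
        rng = np.random.default_rng(8)
        img = render_spatial(
            GaussianSpatialFilter(-0.8, np.array([6.5, 7.5]), np.diag([3.0, 2.0]))
        ) + rng.normal(0, 0.02, (CROP_SIZE, CROP_SIZE))
        fit = fit_dog_posthoc(img)
        from rgcadapt.receptive_fields import _dog_eval

        rows, cols = np.mgrid[0:CROP_SIZE, 0:CROP_SIZE]
        x0 = np.array([0.5, 0.5, 7, 7, 1.2, 1.2, 1e-3 / 1.2**2, 1.5, 1.5, 1e-3 / 1.5**2])
        mse0 = np.mean((_dog_eval(x0, rows.astype(float), cols.astype(float), -1.0) - img) ** 2)
        assert fit.mse <= mse0

    def test_off_polarity_amplitudes_negative(self):
        img = -render_spatial(GaussianSpatialFilter(1.0, np.array([7.0, 7.0]), np.diag([2.0, 2.0])))
        fit = fit_dog_posthoc(img)
        assert fit.a_c < 0 and fit.a_s <= 0

    def test_surround_strength_of_known_dog(self):
        mu = np.array([7.0, 7.0])
        img_params = dict(mu=mu, cov_c=np.diag([1.5, 1.5]), cov_s=np.diag([6.0, 6.0]))
        img = render_spatial(GaussianSpatialFilter(1.0, mu, img_params["cov_c"])) - render_spatial(
            GaussianSpatialFilter(0.3, mu, img_params["cov_s"])
        )
        fit = fit_dog_posthoc(img)
        got = posthoc_surround_strength(fit)
        rendered = fit.render()
        oracle = (-rendered / np.abs(rendered).max()).max()
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got > 0


class TestThresholdMethod:
    def test_level_set_area_matches_analytic_formula(self):
        """20%-of-peak level set of an isotropic Gaussian has area
        2 pi sigma^2 ln 5; pixel count agrees within 10% on a large grid."""
        sigma = 2.0
        n = 49
        mid = (n - 1) / 2
        img = render_spatial(
            GaussianSpatialFilter(1.0, np.array([mid, mid]), np.diag([sigma**2] * 2)), n
        )
        area = threshold_center_size(img, "ON")
        analytic = 2 * np.pi * sigma**2 * np.log(5)
        assert area == pytest.approx(analytic, rel=0.10)

    def test_disconnected_blob_excluded(self):
        img = np.zeros((CROP_SIZE, CROP_SIZE))
        img[7, 7] = 1.0
        img[7, 8] = 0.5
        img[0, 0] = 0.9  # supra-threshold but disconnected
        img[0, 1] = 0.9
        assert threshold_center_size(img, "ON") == 2.0

    def test_sign_symmetry(self):
        img = render_spatial(
            GaussianSpatialFilter(1.0, np.array([7.0, 7.0]), np.diag([3.0, 2.0]))
        ) - 0.2 * render_spatial(
            GaussianSpatialFilter(1.0, np.array([7.0, 7.0]), np.diag([9.0, 8.0]))
        )
        assert threshold_center_size(img, "ON") == threshold_center_size(-img, "OFF")

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            threshold_center_size(np.zeros((CROP_SIZE, CROP_SIZE)), "ON")


class TestSmoothedSurround:
    def test_pure_center_residue_small(self):
        img = render_spatial(
            GaussianSpatialFilter(1.0, np.array([7.0, 7.0]), np.diag([2.0, 2.0]))
        )
        assert smoothed_surround_amplitude(img, "ON") < 0.02

    def test_known_trough_depth_recovered(self):
        from scipy import ndimage

        mu = np.array([7.0, 7.0])
        img = render_spatial(GaussianSpatialFilter(1.0, mu, np.diag([1.5, 1.5]))) - render_spatial(
            GaussianSpatialFilter(0.3, mu, np.diag([6.0, 6.0]))
        )
        got = smoothed_surround_amplitude(img, "ON")
        # dense oracle: same windowing + smoothing computed independently
        win = np.outer(np.kaiser(CROP_SIZE, 7), np.kaiser(CROP_SIZE, 7))
        ref = img * win
        ref = ref / np.abs(ref).max()
        ref = ndimage.gaussian_filter(ref, 1.5)
        assert got == pytest.approx(max(0.0, (-ref).max()), abs=1e-12)
        assert got > 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        img = rng.normal(0, 1, (CROP_SIZE, CROP_SIZE))
        assert smoothed_surround_amplitude(img, "OFF") == pytest.approx(
            smoothed_surround_amplitude(37.5 * img, "OFF")
        )


class TestEstimatorAgreement:
    def test_three_size_estimators_rank_identically(self):
        """On noiseless rendered DoG filters the DoG-parameter, post-hoc-DoG
        and threshold sizes produce the same ranking (Spearman rho = 1)."""
        rng = np.random.default_rng(10)
        s_dog, s_ph, s_th = [], [], []
        for i, sc in enumerate(np.linspace(1.0, 2.7, 10)):
            ecc = 1.0 + 0.06 * (i % 3)
            cov_c = np.diag([sc**2 * ecc, sc**2 / ecc])
            mu = np.array([7.0, 7.0]) + rng.uniform(-0.5, 0.5, 2)
            img = render_spatial(GaussianSpatialFilter(1.0, mu, cov_c)) - render_spatial(
                GaussianSpatialFilter(0.15, mu, 4 * cov_c)
            )
            p = dog_params(cov_c, 4 * cov_c, a2=0.15, mean=mu)
            s_dog.append(center_size_dog(p))
            s_ph.append(posthoc_center_size(fit_dog_posthoc(img)))
            s_th.append(threshold_center_size(img, "ON"))
        assert stats.spearmanr(s_dog, s_ph).statistic == pytest.approx(1.0)
        assert stats.spearmanr(s_dog, s_th).statistic == pytest.approx(1.0)

    def test_surround_estimates_monotone_in_generative_surround(self):
        """Raising the generative surround amplitude never decreases any of
        the three surround estimates."""
        mu = np.array([7.0, 7.0])
        cov_c = np.diag([1.8, 1.8])
        prev = {"dog": -1.0, "posthoc": -1.0, "smooth": -1.0}
        for a2 in (0.0, 0.1, 0.25, 0.4):
            p = dog_params(cov_c, 4 * cov_c, a2=a2, mean=mu)
            rf = build_spatiotemporal_rf(p)
            img = render_spatial(p.g1) - render_spatial(p.g2)
            vals = {
                "dog": surround_amplitude(rf, "ON", center_pixel=(7, 7)),
                "posthoc": posthoc_surround_strength(fit_dog_posthoc(img)),
                "smooth": smoothed_surround_amplitude(img, "ON"),
            }
            for k in vals:
                assert vals[k] >= prev[k] - 1e-9
            prev = vals
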