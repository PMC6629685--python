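import numpy as np
import pytest

from frcrestore import ImageData
from frcrestore.deconv import (
    DeconvTrace,
    RLOptions,
    convolve,
    estimate_background,
    estimate_snr,
    eta_k,
    rl_deconvolve,
    rl_step,
    stopping_check,
    tau1,
    wiener_deconvolve,
)
from frcrestore.psf import make_gaussian_psf
from frcrestore.synthetic import AcquisitionSpec, blur_phantom, make_phantom, simulate_pair


@pytest.fixture
def gauss_psf():
    return make_gaussian_psf(150.0, 50.0)  # 5x5-ish kernel at sigma ~1.3 px


def brute_force_rl_step(estimate, image, kernel, b=0.0):
    """Direct spatial-domain evaluation of the multiplicative update
    with reflect boundaries (independent oracle for rl_step)."""
    c = kernel.shape[0] // 2

    def conv(x, k):
        padded = np.pad(x, c, mode="reflect")
        out = np.zeros_like(x, dtype=float)
        for i in range(x.shape[0]):
            for j in range(x.shape[1]):
                acc = 0.0
                for a in range(k.shape[0]):
                    for d in range(k.shape[1]):
                        acc += k[a, d] * padded[i + 2 * c - a, j + 2 * c - d]
                out[i, j] = acc
        return out

    blurred = conv(estimate, kernel) + b
    ratio = image / np.maximum(blurred, np.finfo(float).eps)
    correction = conv(ratio, kernel[::-1, ::-1])
    return estimate * correction


class TestWiener:
    def test_delta_psf_is_identity(self, rng):
        img = ImageData(rng.uniform(1, 2, (32, 32)), 50.0)
        psf = make_gaussian_psf(1e-3, 50.0, shape=(5, 5))
        out = wiener_deconvolve(img, psf, snr_reg=1e9, clip=False)
        np.testing.assert_allclose(out.pixels, img.pixels, rtol=1e-6)

    def test_linearity_before_clipping(self, rng, gauss_psf):
        img = ImageData(rng.uniform(0, 5, (32, 32)), 50.0)
        scaled = img.with_pixels(3.0 * img.pixels)
        o1 = wiener_deconvolve(img, gauss_psf, snr_reg=10.0, clip=False)
        o3 = wiener_deconvolve(scaled, gauss_psf, snr_reg=10.0, clip=False)
        np.testing.assert_allclose(o3.pixels, 3.0 * o1.pixels, rtol=1e-9)

    def test_noiseless_deblurring_raises_ground_truth_correlation(self):
        spec = AcquisitionSpec(shape=(128, 128), seed=5)
        phantom = make_phantom(spec)
        blurred = blur_phantom(phantom, spec)
        psf = make_gaussian_psf(250.0, 50.0)
        out = wiener_deconvolve(blurred, psf, snr_reg=100.0)
        c = lambda x: np.corrcoef(x.ravel(), phantom.pixels.ravel())[0, 1]
        assert c(out.pixels) > c(blurred.pixels)

    def test_spacing_mismatch_rejected(self, rng):
        img = ImageData(rng.uniform(0, 1, (32, 32)), 40.0)
        with pytest.raises(ValueError, match="spacing"):
            wiener_deconvolve(img, make_gaussian_psf(150.0, 50.0), snr_reg=1.0)


class TestRLStep:
    def test_fixed_point_at_exact_solution(self, rng, gauss_psf):
        o = np.zeros((48, 48))
        o[16:32, 16:32] = rng.uniform(1, 5, (16, 16))
        i = convolve(o, gauss_psf.kernel)
        out = rl_step(o, i, gauss_psf, b=0.0, tv_lambda=0.0)
        np.testing.assert_allclose(out, o, atol=1e-9 * o.max())

    def test_flux_conservation(self, rng, gauss_psf):
        # content away from the borders: total intensity preserved
        i = np.zeros((48, 48))
        i[12:36, 12:36] = rng.uniform(1, 10, (24, 24))
        i = convolve(i, gauss_psf.kernel)
        out = rl_step(i.copy(), i, gauss_psf)
        assert out.sum() == pytest.approx(i.sum(), rel=1e-6)

    def test_matches_brute_force_oracle(self, rng, gauss_psf):
        est = rng.uniform(0.5, 3.0, (16, 16))
        img = rng.uniform(0.5, 3.0, (16, 16))
        expected = brute_force_rl_step(est, img, gauss_psf.kernel, b=0.3)
        out = rl_step(est, img, gauss_psf, b=0.3)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_non_negativity(self, rng, gauss_psf):
        est = rng.uniform(0, 2, (32, 32))
        img = rng.uniform(0, 2, (32, 32))
        out = rl_step(est, img, gauss_psf, tv_lambda=5e-4)
        assert np.all(out >= 0)

    def test_all_zero_estimate_rejected(self, gauss_psf):
        with pytest.raises(ValueError, match="zero"):
            rl_step(np.zeros((16, 16)), np.ones((16, 16)), gauss_psf)

    def test_tv_regularization_changes_update(self, rng, gauss_psf):
        est = rng.uniform(0.5, 3.0, (32, 32))
        img = rng.uniform(0.5, 3.0, (32, 32))
        plain = rl_step(est, img, gauss_psf, tv_lambda=0.0)
        tv = rl_step(est, img, gauss_psf, tv_lambda=5e-4)
        assert not np.allclose(plain, tv)


class TestConvergenceMetrics:
    def test_tau1_identical_estimates(self, rng):
        x = rng.uniform(0, 1, (8, 8))
        assert tau1(x, x.copy()) == 0.0

    def test_tau1_doubling(self):
        prev = np.full((4, 4), 2.0)
        assert tau1(2 * prev, prev) == pytest.approx(0.5)

    def test_tau1_hand_arithmetic(self):
        assert tau1(np.array([1.0, 3.0]), np.array([2.0, 2.0])) == pytest.approx(0.5)

    def test_tau1_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            tau1(np.zeros((4, 4)), np.ones((4, 4)))

    def test_eta_converged_is_zero(self, rng, gauss_psf):
        o = rng.uniform(1, 5, (48, 48))  # support everywhere: ratio is 1
        i = convolve(o, gauss_psf.kernel)
        assert eta_k(i, o, gauss_psf) == 0.0

    def test_eta_ratio_half_everywhere_is_one(self, rng, gauss_psf):
        o = rng.uniform(1, 5, (48, 48))
        i = 0.5 * convolve(o, gauss_psf.kernel)
        assert eta_k(i, o, gauss_psf, epsilon=0.05) == 1.0

    def test_eta_counts_fraction(self):
        delta = make_gaussian_psf(1e-3, 50.0, shape=(1, 1))
        o = np.ones((16, 16))
        i = np.ones((16, 16))
        i[:8] = 0.5  # half converged at 1, half in the middle band
        assert eta_k(i, o, delta, epsilon=0.05) == pytest.approx(0.5)

    def test_eta_invalid_epsilon(self, gauss_psf):
        with pytest.raises(ValueError):
            eta_k(np.ones((8, 8)), np.ones((8, 8)), gauss_psf, epsilon=0.7)


class TestBackgroundEstimation:
    def test_two_level_image(self):
        px = np.full((32, 32), 10.0)
        px[8:24, 8:24] = 100.0
        assert estimate_background(ImageData(px, 50.0)) == pytest.approx(10.0)

    def test_constant_image_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            b = estimate_background(ImageData(np.full((16, 16), 7.0), 50.0))
        assert b == 7.0

    def test_noisy_background_recovered(self):
        estimates = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            px = r.normal(10.0, 2.0, (64, 64))
            px[16:48, 16:48] = 100.0
            estimates.append(estimate_background(ImageData(np.clip(px, 0, None), 50.0)))
        n_bg = 64 * 64 - 32 * 32
        se = 2.0 / np.sqrt(n_bg * len(estimates))
        assert abs(np.mean(estimates) - 10.0) <= 3 * se + 0.05

    def test_snr_estimate_positive(self, rng):
        img = ImageData(rng.poisson(50, (64, 64)).astype(float), 50.0)
        assert estimate_snr(img) >= 1e-3


def _trace_from_dmin(values):
    trace = DeconvTrace()
    for v in values:
        trace.append(v, 0.0, 0.0)
    return trace


class TestStoppingCheck:
    def test_threshold_reached(self):
        trace = _trace_from_dmin([300.0, 260.0, 240.0, 239.5])
        decision, reason = stopping_check(trace, RLOptions(stop_grad_threshold=-1.0))
        assert (decision, reason) == ("stop", "threshold_reached")

    def test_steep_trace_continues(self):
        trace = _trace_from_dmin([300.0, 260.0, 230.0, 210.0])
        decision, _ = stopping_check(trace, RLOptions(stop_grad_threshold=-1.0, max_iter=99))
        assert decision == "continue"

    def test_failsafe_on_trend_reversal(self):
        trace = _trace_from_dmin([300.0, 250.0, 240.0, 260.0])
        decision, reason = stopping_check(trace, RLOptions(stop_grad_threshold=-1.0))
        assert (decision, reason) == ("stop", "failsafe_grad2")

    def test_max_resolution_reason_at_zero_threshold(self):
        trace = _trace_from_dmin([300.0, 260.0, 260.1])
        decision, reason = stopping_check(
            trace, RLOptions(stop_grad_threshold=0.0, failsafe=False)
        )
        assert (decision, reason) == ("stop", "max_resolution")

    def test_max_iter_stop(self):
        trace = _trace_from_dmin([300.0, 260.0, 230.0])
        decision, reason = stopping_check(
            trace, RLOptions(stop_grad_threshold=-np.inf, max_iter=3, failsafe=False)
        )
        assert (decision, reason) == ("stop", "max_iter")

    def test_grad_bookkeeping(self):
        trace = _trace_from_dmin([300.0, 260.0, 240.0])
        np.testing.assert_allclose(trace.grad[1:], [-40.0, -20.0])
        np.testing.assert_allclose(trace.grad2[2:], [20.0])

    def test_positive_threshold_rejected(self):
        with pytest.raises(ValueError):
            RLOptions(stop_grad_threshold=0.5)


class TestRLDeconvolve:
    def test_fixed_iteration_count(self, sim_pair):
        _, a, _ = sim_pair
        options = RLOptions(max_iter=5, stop_grad_threshold=-np.inf, failsafe=False)
        _, trace = rl_deconvolve(a, "auto", options)
        assert trace.iterations == [1, 2, 3, 4, 5]
        assert trace.stop_reason == "max_iter"

    def test_estimates_stay_non_negative(self, sim_pair):
        _, a, _ = sim_pair
        options = RLOptions(max_iter=3, stop_grad_threshold=-np.inf, failsafe=False)
        restored, _ = rl_deconvolve(a, "auto", options)
        assert np.all(restored.pixels >= 0)

    def test_resolution_improves_on_noisy_blurred_phantom(self, sim_pair, calibration):
        _, a, _ = sim_pair
        options = RLOptions(max_iter=20, stop_grad_threshold=-1.0, calibration=calibration)
        _, trace = rl_deconvolve(a, "auto", options)
        from frcrestore.frc import one_image_frc

        _, input_res = one_image_frc(a, calibration=calibration)
        assert trace.d_min_nm[-1] <= input_res.d_min_nm

    def test_background_term_accepted(self, sim_pair):
        phantom, a, _ = sim_pair
        bumped = a.with_pixels(a.pixels + 20.0)
        options = RLOptions(max_iter=2, stop_grad_threshold=-np.inf,
                            failsafe=False, background="auto")
        restored, trace = rl_deconvolve(bumped, "auto", options)
        assert len(trace.iterations) == 2

    def test_tau1_eventually_decreases(self, sim_pair):
        _, a, _ = sim_pair
        options = RLOptions(max_iter=12, stop_grad_threshold=-np.inf, failsafe=False)
        _, trace = rl_deconvolve(a, "auto", options)
        tail = trace.tau1[-3:]
        assert all(np.diff(tail) <= 1e-12)

    def test_trace_dataframe_columns(self, sim_pair):
        _, a, _ = sim_pair
        options = RLOptions(max_iter=2, stop_grad_threshold=-np.inf, failsafe=False)
        _, trace = rl_deconvolve(a, "auto", options)
        df = trace.to_dataframe()
        assert list(df.columns) == ["iteration", "d_min_nm", "grad", "grad2", "tau1", "eta"]
        assert len(df) == 2
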