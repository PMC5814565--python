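import numpy as np
import pytest

from pulsebeta import (
    BeatWindow,
    ConfigError,
    DerivativeSpec,
    EstimationConfig,
    EstimationError,
    ViscoelasticParams,
    compute_derivatives,
    estimate_record,
    estimate_step1,
    estimate_step2,
    forward_bp,
    reconstruct_and_score,
)
from pulsebeta.estimate import estimate_beat
from pulsebeta.synth import PPGPulse


def make_exact_beat(mu=0.02, eta=0.3, beta=0.5, p_b0=np.log(60.0),
                    period=0.857, fs=1000.0, amplitude=1.0):
    """One beat generated exactly from the forward model with analytic
    PPG derivatives: the estimator's identifiable ideal case."""
    pulse = PPGPulse(period=period, amplitude=amplitude)
    n = int(round(period * fs))
    t = np.arange(n) / fs
    ppg, d1, d2 = pulse.evaluate(t)
    params = ViscoelasticParams(mu=mu, eta=eta, beta=beta, p_b0=p_b0)
    bp = forward_bp(ppg, d1, d2, params)
    return bp, ppg, d1, d2, params


class TestDerivatives:
    def test_constant_signal_has_zero_derivatives(self):
        d1, d2 = compute_derivatives(np.full(500, 3.0), 1000.0)
        assert np.allclose(d1, 0.0, atol=1e-9)
        assert np.allclose(d2, 0.0, atol=1e-6)

    def test_ramp_has_unit_slope(self):
        t = np.arange(500) / 1000.0
        d1, d2 = compute_derivatives(t, 1000.0)
        interior = slice(30, -30)
        assert np.allclose(d1[interior], 1.0, rtol=1e-9)
        assert np.allclose(d2[interior], 0.0, atol=1e-5)

    def test_sine_derivative_matches_analytic(self):
        fs, f = 1000.0, 1.2
        t = np.arange(5000) / fs
        d1, _ = compute_derivatives(np.sin(2 * np.pi * f * t), fs)
        want = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        interior = slice(50, -50)
        err = np.abs(d1[interior] - want[interior]) / (2 * np.pi * f)
        assert err.max() < 0.005

    def test_linearity(self, rng):
        fs = 1000.0
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        dx1, dx2 = compute_derivatives(x, fs)
        dy1, dy2 = compute_derivatives(y, fs)
        ds1, ds2 = compute_derivatives(2 * x + 3 * y, fs)
        assert np.allclose(ds1, 2 * dx1 + 3 * dy1, rtol=1e-10, atol=1e-10)
        assert np.allclose(ds2, 2 * dx2 + 3 * dy2, rtol=1e-10, atol=1e-8)

    def test_window_shorter_than_order_rejected(self):
        with pytest.raises(ConfigError):
            DerivativeSpec(window_ms=2.0, polyorder=5).window_samples(1000.0)

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ConfigError):
            compute_derivatives(np.zeros(10), 1000.0)


class TestStep1:
    def test_exact_recovery_on_linear_model(self, rng):
        # data generated from the differenced linear model itself
        n, i0 = 300, 0
        ppg = rng.normal(0.0, 0.5, n)
        d1 = rng.normal(0.0, 5.0, n)
        d2 = rng.normal(0.0, 100.0, n)
        mu, eta, beta_A = 0.05, 0.8, 60.0
        bp = 90.0 + mu * (d2 - d2[i0]) + eta * (d1 - d1[i0]) \
            + beta_A * (ppg - ppg[i0])
        got = estimate_step1(bp, ppg, d1, d2, i0)
        assert got == pytest.approx((mu, eta, beta_A), rel=1e-9)

    def test_matches_normal_equations(self, rng):
        for _ in range(20):
            n, i0 = 200, 0
            ppg = rng.normal(0.0, 0.5, n)
            d1 = rng.normal(0.0, 5.0, n)
            d2 = rng.normal(0.0, 100.0, n)
            bp = 80.0 + rng.normal(0.0, 5.0, n)
            got = np.array(estimate_step1(bp, ppg, d1, d2, i0))
            X = np.column_stack([d2 - d2[i0], d1 - d1[i0], ppg - ppg[i0]])
            y = bp - bp[i0]
            want = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(got, want, rtol=1e-10, atol=1e-10)

    def test_flat_ppg_is_rank_deficient(self):
        n = 100
        with pytest.raises(EstimationError):
            estimate_step1(np.full(n, 80.0), np.full(n, 0.5),
                           np.zeros(n), np.zeros(n), 0)

    def test_beats_coarse_grid_search(self, rng):
        # the LS solution attains a lower SSE than every point of a
        # coarse lattice around the truth
        n, i0 = 50, 0
        ppg = rng.normal(0.0, 0.5, n)
        d1 = rng.normal(0.0, 5.0, n)
        d2 = rng.normal(0.0, 100.0, n)
        true = np.array([0.05, 0.8, 60.0])
        bp = 90.0 + true[0] * (d2 - d2[i0]) + true[1] * (d1 - d1[i0]) \
            + true[2] * (ppg - ppg[i0]) + rng.normal(0.0, 0.5, n)
        X = np.column_stack([d2 - d2[i0], d1 - d1[i0], ppg - ppg[i0]])
        y = bp - bp[i0]

        def sse(theta):
            return float(np.sum((y - X @ theta) ** 2))

        got = np.array(estimate_step1(bp, ppg, d1, d2, i0))
        grid_best = min(
            sse(true * np.array([1 + a, 1 + b, 1 + c]))
            for a in np.linspace(-0.05, 0.05, 7)
            for b in np.linspace(-0.05, 0.05, 7)
            for c in np.linspace(-0.05, 0.05, 7))
        assert sse(got) <= grid_best * (1 + 1e-12)


class TestStep2:
    def test_constructed_exponential_identity(self, rng):
        # q(t) = q(t0) * exp(2 dPl(t)) exactly -> beta = 2
        n, i0 = 200, 0
        ppg = np.linspace(0.0, 1.0, n)
        q0 = 60.0
        bp = q0 * np.exp(2.0 * (ppg - ppg[i0]))
        z = np.zeros(n)
        beta, n_masked, _, _ = estimate_step2(bp, ppg, z, z, mu=0.0, eta=0.0,
                                              i0=i0, mean_bp=bp.min() - 1.0)
        assert beta == pytest.approx(2.0, rel=1e-12)
        assert n_masked == n

    def test_exact_beat_recovery_with_true_mechanics(self):
        bp, ppg, d1, d2, params = make_exact_beat()
        beta, _, mask, _ = estimate_step2(bp, ppg, d1, d2, params.mu,
                                          params.eta, 0, float(bp.mean()))
        assert beta == pytest.approx(params.beta, rel=1e-9)

    def test_empty_mask_flags_invalid(self):
        # an empty above-mean/positive-residual mask must flag the beat
        bp, ppg, d1, d2, params = make_exact_beat()
        with pytest.raises(EstimationError):
            estimate_step2(bp, ppg, d1, d2, mu=params.mu, eta=params.eta,
                           i0=0, mean_bp=float(bp.max()) + 1.0)

    def test_reference_shift_when_q_nonpositive_at_t0(self):
        bp, ppg, d1, d2, params = make_exact_beat()
        bp = bp.copy()
        bp[0] = -1.0  # corrupt the reference sample only
        beta, _, _, ref = estimate_step2(bp, ppg, d1, d2, params.mu,
                                         params.eta, 0, float(bp.mean()))
        assert ref != 0
        assert beta == pytest.approx(params.beta, rel=1e-6)


class TestReconstruction:
    def test_noiseless_beat_scores_near_one(self):
        bp, ppg, d1, d2, params = make_exact_beat()
        beta, _, mask, _ = estimate_step2(bp, ppg, d1, d2, params.mu,
                                          params.eta, 0, float(bp.mean()))
        intercept, r2 = reconstruct_and_score(bp, ppg, d1, d2, params.mu,
                                              params.eta, beta, mask)
        assert r2 > 0.999
        assert intercept == pytest.approx(params.p_b0, rel=1e-6)

    def test_heavy_noise_fails_gate(self, rng):
        bp, ppg, d1, d2, params = make_exact_beat()
        noisy = bp + rng.normal(0.0, 20.0, bp.size)
        beat = BeatWindow(index=0, start_sample=0, end_sample=bp.size,
                          t0_sample=0, mean_bp=float(noisy.mean()))
        est = estimate_beat(noisy, ppg, d1, d2, beat,
                            float(noisy.mean()), EstimationConfig())
        assert not est.accepted


class TestRecordEstimation:
    def test_noiseless_pipeline_recovers_beta(self, rest_record, rest_beats,
                                              truth):
        record, ledger = rest_record
        estimates = estimate_record(record, rest_beats)
        ok = [e for e in estimates if e.valid]
        assert len(ok) == len(rest_beats)
        errs = [abs(e.beta - truth.beta) / truth.beta for e in ok]
        assert np.median(errs) < 1e-3
        assert all(e.accepted for e in ok)

    def test_nan_beats_isolated(self, rest_record, rest_beats):
        record, _ = rest_record
        bad_bp = record.bp.copy()
        for b in rest_beats[:2]:
            bad_bp[b.start_sample:b.start_sample + 10] = np.nan
        from pulsebeta import WaveformRecord
        corrupted = WaveformRecord.__new__(WaveformRecord)
        corrupted.time, corrupted.ecg = record.time, record.ecg
        corrupted.bp, corrupted.ppg = bad_bp, record.ppg
        corrupted.fs, corrupted.meta = record.fs, record.meta
        estimates = estimate_record(corrupted, rest_beats,
                                    EstimationConfig(smooth_signals=False))
        assert sum(not e.valid for e in estimates) == 2
        assert sum(e.valid for e in estimates) == len(rest_beats) - 2

    def test_single_pass_matches_textbook_two_step(self):
        # max_refine=0 must reproduce the plain composition of the
        # two step functions
        bp, ppg, d1, d2, params = make_exact_beat()
        beat = BeatWindow(index=0, start_sample=0, end_sample=bp.size,
                          t0_sample=0, mean_bp=float(bp.mean()))
        cfg = EstimationConfig(max_refine=0, smooth_signals=False)
        est = estimate_beat(bp, ppg, d1, d2, beat, beat.mean_bp, cfg)
        mu, eta, beta_A = estimate_step1(bp, ppg, d1, d2, 0)
        beta, _, _, _ = estimate_step2(bp, ppg, d1, d2, mu, eta, 0,
                                       beat.mean_bp)
        assert est.mu == pytest.approx(mu, rel=1e-12)
        assert est.beta == pytest.approx(beta, rel=1e-12)


class TestInvariances:
    def test_constant_bp_offset_leaves_step1_unchanged(self, rng):
        bp, ppg, d1, d2, _ = make_exact_beat()
        a = estimate_step1(bp, ppg, d1, d2, 0)
        b = estimate_step1(bp + 25.0, ppg, d1, d2, 0)
        assert np.allclose(a, b, rtol=1e-9)

    def test_ppg_gain_rescales_parameters(self):
        # multiplying P_l by k divides mu, eta, beta_A and beta by k
        bp, ppg, d1, d2, params = make_exact_beat()
        k = 2.5
        mu1, eta1, bA1 = estimate_step1(bp, ppg, d1, d2, 0)
        mu2, eta2, bA2 = estimate_step1(bp, k * ppg, k * d1, k * d2, 0)
        assert (mu2, eta2, bA2) == pytest.approx(
            (mu1 / k, eta1 / k, bA1 / k), rel=1e-9)
        beta1, _, _, _ = estimate_step2(bp, ppg, d1, d2, mu1, eta1, 0,
                                        float(bp.mean()))
        beta2, _, _, _ = estimate_step2(bp, k * ppg, k * d1, k * d2,
                                        mu2, eta2, 0, float(bp.mean()))
        assert beta2 == pytest.approx(beta1 / k, rel=1e-9)
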