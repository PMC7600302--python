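"""Indicator oracles: Welch PSD, spectral-model recovery, xi1, ERD/ERS, xi2."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mieff
from mieff.containers import CONFIG_2CH, TrialSet, TrialTiming
from mieff.indicators import (ERDSTimeCourse, PSDEstimate, compute_xi2, erds,
                              fit_psd_model, pair_distance, run_trend_test,
                              welch_psd, xi1, xi2)
from mieff.synth import simulate_trial_set


def _gauss(f, k, m, s):
    return k * np.exp(-0.5 * ((f - m) / s) ** 2)


@pytest.fixture(scope="module")
def constructed_psd():
    f = np.arange(4.0, 40.5, 0.5)
    s = _gauss(f, 2, 10, 1.5) + _gauss(f, 1, 22, 3) + 0.5 + 10 / f
    return PSDEstimate(f, s)


class TestWelch:
    def test_peak_at_tone_frequency(self):
        fs = 160.0
        t = np.arange(int(8 * fs)) / fs
        psd = welch_psd(np.sin(2 * np.pi * 10 * t), fs)
        assert psd.frequencies[np.argmax(psd.power)] == pytest.approx(10.0, abs=1.0)

    def test_white_noise_total_power(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.0, size=160 * 60)
        psd = welch_psd(x, 160.0)
        total = np.trapezoid(psd.power, psd.frequencies)
        assert total == pytest.approx(4.0, rel=0.1)

    def test_constant_signal_has_no_band_power(self):
        psd = welch_psd(np.full(1600, 3.0), 160.0).restrict(4, 40)
        assert np.allclose(psd.power, 0, atol=1e-12)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), 160.0)


class TestPSDFit:
    def test_recovers_constructed_spectrum(self, constructed_psd):
        fit = fit_psd_model(constructed_psd)
        assert 9.5 <= fit.m_mu <= 10.5
        assert 21 <= fit.m_beta <= 23
        assert fit.residual < 1e-3 * np.linalg.norm(constructed_psd.power)

    def test_pure_noise_gives_null_peaks(self):
        f = np.arange(4.0, 40.5, 0.5)
        psd = PSDEstimate(f, 0.5 + 10 / f)
        fit = fit_psd_model(psd)
        assert fit.k_mu == pytest.approx(0.0, abs=0.02)
        assert fit.k_beta == pytest.approx(0.0, abs=0.02)
        assert fit.residual < 1e-3 * np.linalg.norm(psd.power)

    def test_objective_homogeneity_under_scaling(self, constructed_psd):
        fit1 = fit_psd_model(constructed_psd)
        scaled = PSDEstimate(constructed_psd.frequencies, 3 * constructed_psd.power)
        fit3 = fit_psd_model(scaled)
        assert fit3.k_mu == pytest.approx(3 * fit1.k_mu, rel=0.05)
        assert fit3.kappa2 == pytest.approx(3 * fit1.kappa2, rel=0.05)
        assert fit3.m_mu == pytest.approx(fit1.m_mu, abs=0.1)
        assert fit3.eta == pytest.approx(fit1.eta, abs=0.05)

    def test_multistart_never_increases_residual(self, constructed_psd):
        r1 = fit_psd_model(constructed_psd, n_starts=1).residual
        r5 = fit_psd_model(constructed_psd, n_starts=5).residual
        assert r5 <= r1 + 1e-12


class TestXi1:
    def test_zero_when_psd_equals_noise(self):
        f = np.arange(4.0, 40.5, 0.5)
        psd = PSDEstimate(f, 0.5 + 10 / f)
        fit = fit_psd_model(psd)
        assert xi1([psd], [fit]) == pytest.approx(0.0, abs=0.02)

    def test_equals_gaussian_peak_height(self):
        f = np.arange(4.0, 40.25, 0.25)
        psd = PSDEstimate(f, 0.5 + 10 / f + _gauss(f, 1, 10, 1.5))
        fit = fit_psd_model(psd)
        assert xi1([psd], [fit]) == pytest.approx(1.0, abs=0.05)

    def test_increases_with_peak_amplitude(self):
        f = np.arange(4.0, 40.5, 0.5)
        vals = []
        for k in (1.0, 2.0):
            psd = PSDEstimate(f, 0.5 + 10 / f + _gauss(f, k, 10, 1.5))
            vals.append(xi1([psd], [fit_psd_model(psd)]))
        assert vals[1] > vals[0]

    def test_invariant_to_channel_order(self, constructed_psd):
        f = constructed_psd.frequencies
        other = PSDEstimate(f, 0.5 + 8 / f + _gauss(f, 1.5, 11, 1.0))
        fits = [fit_psd_model(p) for p in (constructed_psd, other)]
        a = xi1([constructed_psd, other], fits)
        b = xi1([other, constructed_psd], fits[::-1])
        assert a == pytest.approx(b)

    def test_grid_mismatch_rejected(self, constructed_psd):
        f = np.arange(4.0, 40.0, 1.0)
        other = PSDEstimate(f, 0.5 + 10 / f)
        with pytest.raises(ValueError):
            xi1([constructed_psd, other],
                [fit_psd_model(constructed_psd), fit_psd_model(other)])


def _power_scaled_trials(alpha, n_trials=100, fs=160.0, seed=0):
    """Band-limited noise trials whose MI-interval power is alpha x baseline."""
    from scipy.signal import butter, sosfiltfilt

    rng = np.random.default_rng(seed)
    timing = TrialTiming()
    n = int(timing.trial_length_s * fs)
    sos = butter(4, [4, 40], btype="band", fs=fs, output="sos")
    t = np.arange(n) / fs
    m0, m1 = timing.mi_interval_s
    gain = np.where((t >= m0) & (t < m1), np.sqrt(alpha), 1.0)
    data = np.empty((2 * n_trials, 1, n))
    for i in range(2 * n_trials):
        x = sosfiltfilt(sos, rng.normal(size=n))
        data[i, 0] = x * gain
    labels = np.array(["left", "right"] * n_trials)
    return TrialSet(data, labels, fs, timing, ("C3",))


class TestERDS:
    def test_constant_power_gives_flat_curve(self):
        timing = TrialTiming()
        fs = 160.0
        n = int(timing.trial_length_s * fs)
        data = np.full((4, 1, n), 3.0)
        ts = TrialSet(data, np.array(["left", "right"] * 2), fs, timing, ("C3",))
        tc = erds(ts, "mu", "C3", prefiltered=True)
        assert np.allclose(tc["left"].zhat, 0.0)
        assert np.allclose(tc["right"].zhat_masked, 0.0)

    @pytest.mark.parametrize("alpha", [0.5, 2.0])
    def test_power_scaling_recovered(self, alpha):
        ts = _power_scaled_trials(alpha)
        tc = erds(ts, "mu", "C3", prefiltered=True)
        mid = tc["left"].crop(2.8, 4.4, masked=False)
        assert mid.mean() == pytest.approx(alpha - 1, abs=0.1)

    def test_generator_erd_depth_recovered(self, mid_trials):
        tc = erds(mid_trials, "mu", "C3")
        mi = tc["right"].crop(2.8, 4.4, masked=False)
        assert mi.mean() == pytest.approx(-0.5, abs=0.1)

    def test_curve_bounded_below_by_minus_one(self, mid_trials):
        for band in ("mu", "beta"):
            tc = erds(mid_trials, band, "C4")
            for c in tc.values():
                assert (c.zhat >= -1 - 1e-12).all()

    def test_missing_class_rejected(self, mid_trials):
        only_left = mid_trials.subset(mid_trials.labels == "left")
        with pytest.raises(ValueError):
            erds(only_left, "mu", "C3")


class TestXi2:
    def test_identical_curves_give_zero(self):
        c = np.array([0.3, -0.2, 0.5])
        assert xi2({("mu", "C3"): {"left": c, "right": c.copy()}}) == 0.0

    def test_printed_two_sample_toy(self):
        assert pair_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(2.0)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_common_positive_scaling(self, s):
        a = np.array([1.0, -0.5, 0.25])
        b = np.array([-0.2, 0.7, 0.1])
        assert pair_distance(s * a, s * b) == pytest.approx(pair_distance(a, b), rel=1e-9)

    def test_symmetric_in_class_swap(self):
        a = np.array([1.0, -0.5, 0.25])
        b = np.array([-0.2, 0.7, 0.1])
        assert pair_distance(a, b) == pytest.approx(pair_distance(b, a))

    def test_matches_brute_force_on_stored_curves(self, mid_trials):
        res = compute_xi2(mid_trials, CONFIG_2CH, ("mu", "beta"))
        m0, m1 = mid_trials.timing.mi_interval_s
        brute = -np.inf
        for pair, curves in res.curves.items():
            a = curves["left"].crop(m0, m1)
            b = curves["right"].crop(m0, m1)
            if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
                continue  # degenerate pair, skipped by contract
            d = np.sum((a - b) ** 2) / (np.linalg.norm(a) * np.linalg.norm(b))
            brute = max(brute, d)
        assert res.value == pytest.approx(brute)

    def test_nonnegative(self, mid_trials):
        assert compute_xi2(mid_trials, CONFIG_2CH).value >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pair_distance(np.ones(3), np.ones(4))


class TestRunTrend:
    @pytest.fixture(scope="class")
    def decaying_cohort(self):
        """6 subjects whose ERD depth decays 0.8 -> 0.5 -> 0.3 over runs."""
        cohort = []
        for m in range(6):
            base = mieff.make_cohort(1, seed=100 + m, efficiency_spec=[1.0])[0]
            runs = []
            for r, depth in enumerate((0.8, 0.5, 0.3)):
                prof = dataclasses.replace(base, erd_depth=depth, seed=base.seed + r)
                runs.append(simulate_trial_set(prof, n_trials=30))
            data = np.concatenate([ts.data for ts in runs])
            labels = np.concatenate([ts.labels for ts in runs])
            cohort.append(TrialSet(data, labels, runs[0].fs, runs[0].timing,
                                   runs[0].channels, runs[0].montage))
        return cohort

    def test_mean_xi2_decreases_with_decaying_erd(self, decaying_cohort):
        res = run_trend_test(decaying_cohort, run_size=60)
        assert res.xi2_per_run.shape == (6, 3)
        assert res.run_means[0] > res.run_means[1] > res.run_means[2]

    def test_single_run_rejected(self, decaying_cohort):
        with pytest.raises(ValueError):
            run_trend_test(decaying_cohort, run_size=120)

    def test_identical_runs_not_significant(self):
        """Runs drawn from one stationary process should rarely differ."""
        non_sig = 0
        reps = 8
        for rep in range(reps):
            cohort = []
            for m in range(8):
                prof = mieff.make_cohort(1, seed=500 + 20 * rep + m,
                                         efficiency_spec=[0.6])[0]
                cohort.append(simulate_trial_set(prof, n_trials=10))
            res = run_trend_test(cohort, run_size=10, max_runs=2)
            non_sig += res.p_values[0] > 0.05
        assert non_sig >= reps - 1
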