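"""Unit and property tests for the two-stage T6SS kinetic model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from t6sim import kinetics as K


# ---------------------------------------------------------------------------
# Closed forms


class TestActivationProbability:
    @pytest.mark.parametrize(
        "params, t, expected",
        [
            ((0.10, 1.34, 0.118), 1.0, 0.10),  # inside the waiting period
            ((0.10, 1.34, 0.118), 0.0, 0.10),
            ((0.30, 2.0, 0.0), 50.0, 0.30),  # no switching at zero rate
            ((0.0, 0.0, 1e9), 0.5, 1.0),  # instant saturation limit
        ],
    )
    def test_branch_values(self, params, t, expected):
        p = K.KineticParams(*params)
        assert K.activation_probability(p, t) == pytest.approx(expected, abs=1e-12)

    def test_negative_time_rejected(self, es401_fit_params):
        with pytest.raises(ValueError):
            K.activation_probability(es401_fit_params, -0.1)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        p0=st.floats(0.0, 1.0),
        tau=st.floats(0.0, 5.0),
        lam=st.floats(0.0, 5.0),
        t=st.floats(0.0, 50.0),
        dt=st.floats(0.0, 10.0),
    )
    def test_monotone_bounded(self, p0, tau, lam, t, dt):
        p = K.KineticParams(p0, tau, lam)
        a = K.activation_probability(p, t)
        b = K.activation_probability(p, t + dt)
        assert p0 - 1e-12 <= a <= 1.0 + 1e-12
        assert b >= a - 1e-12
        if t < tau:
            assert a == pytest.approx(p0)

    def test_matches_tau_leap_ensemble(self, es401_fit_params, rng):
        """Stochastic switching reproduces the closed form (binomial error)."""
        n = 100_000
        frac = K.simulate_activation_ensemble(es401_fit_params, n, 3.0, 0.01, rng)
        expected = K.activation_probability(es401_fit_params, 3.0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 4 * se


class TestSteadyState:
    @pytest.mark.parametrize(
        "lam_s, lam_f, expected", [(21.0, 6.0, 3.5), (0.0, 1.0, 0.0), (20.0, 20.0, 1.0)]
    )
    def test_mean(self, lam_s, lam_f, expected):
        p = K.KineticParams(0.0, 0.0, 0.0, lam_s, lam_f)
        assert K.steady_state_mean(p) == expected

    def test_no_finite_steady_state(self):
        with pytest.raises(ValueError):
            K.steady_state_mean(K.KineticParams(0.0, 0.0, 0.0, 21.0, 0.0))

    def test_firing_rate_from_target_mean(self):
        assert K.firing_rate_for_mean(21.0, 3.5) == 6.0


# ---------------------------------------------------------------------------
# Single-reactor stepping


class TestStepActivation:
    def test_waits_out_the_delay(self, rng):
        p = K.KineticParams(0.0, 1.0, 5.0)
        state = K.ReactorState(G=False, N=0, t=0.5)
        for _ in range(200):
            out = K.step_activation(state, p, 0.02, rng)
            assert not out.G  # t=0.5 < tau_plus regardless of lambda_plus
        assert out.t == pytest.approx(0.52)

    def test_zero_rate_never_switches(self, rng):
        p = K.KineticParams(0.0, 0.0, 0.0)
        state = K.ReactorState(G=False, N=0, t=5.0)
        for _ in range(100):
            state = K.step_activation(state, p, 0.05, rng)
        assert not state.G

    def test_tau_leap_bound_enforced(self, rng):
        p = K.KineticParams(0.0, 0.0, 5.0)
        with pytest.raises(ValueError):
            K.step_activation(K.ReactorState(t=1.0), p, 0.5, rng)


class TestStepSheathDynamics:
    def test_no_reactions_at_zero_rates(self, rng):
        p = K.KineticParams(0.0, 0.0, 0.0, 0.0, 0.0)
        state, fired = K.step_sheath_dynamics(K.ReactorState(G=True, N=5), p, 0.01, rng)
        assert state.N == 5 and fired == 0

    def test_inactive_reactor_frozen(self, rng, wt_kinetics):
        state, fired = K.step_sheath_dynamics(
            K.ReactorState(G=False, N=3), wt_kinetics, 0.004, rng
        )
        assert state.N == 3 and fired == 0

    def test_rate_dt_bound(self, rng, wt_kinetics):
        with pytest.raises(ValueError):
            K.step_sheath_dynamics(K.ReactorState(G=True), wt_kinetics, 0.05, rng)

    def test_nonfiring_strain_never_fires(self, rng):
        p = K.KineticParams(0.0, 0.0, 0.0, 21.0, 0.0)
        state = K.ReactorState(G=True, N=0)
        total_fired = 0
        for _ in range(500):
            state, fired = K.step_sheath_dynamics(state, p, 0.004, rng)
            total_fired += fired
        assert total_fired == 0
        assert state.N > 0  # synthesis still runs

    @pytest.mark.parametrize("lam_s, lam_f", [(21.0, 6.0), (20.0, 20.0), (10.0, 5.0)])
    def test_long_run_matches_poisson_steady_state(self, lam_s, lam_f, rng):
        """Tau-leap ensembles settle onto the Poisson(lambda_s/lambda_f) law."""
        p = K.KineticParams(1.0, 0.0, 0.0, lam_s, lam_f)
        n, dt = 500, 0.004
        states = [K.ReactorState(G=True, N=0) for _ in range(n)]
        for _ in range(int(2.0 / dt)):
            states = [K.step_sheath_dynamics(s, p, dt, rng)[0] for s in states]
        hist = K.SheathHistogram.from_samples([s.N for s in states])
        _, pval = K.poisson_gof_test(hist)
        assert pval > 0.001
        se = np.sqrt(lam_s / lam_f / n)
        assert abs(hist.mean - lam_s / lam_f) < 4 * se

    def test_tau_leap_consistent_with_exact_ssa(self, rng, wt_kinetics):
        """Transient tau-leap distribution agrees with the exact simulation."""
        p = K.KineticParams(1.0, 0.0, 0.0, 21.0, 6.0)
        n, dt, t_end = 2000, 0.004, 0.4
        states = [K.ReactorState(G=True, N=0) for _ in range(n)]
        for _ in range(int(t_end / dt)):
            states = [K.step_sheath_dynamics(s, p, dt, rng)[0] for s in states]
        leap = np.array([s.N for s in states])
        exact = K.sample_sheath_counts(p, t_end, 20_000, rng, primed=True)
        res = stats.ks_2samp(leap, exact)
        assert res.pvalue > 0.001


class TestExactSSA:
    def test_ensemble_mean_reaches_steady_state(self, rng):
        p = K.KineticParams(1.0, 0.0, 0.0, 21.0, 6.0)
        counts = K.sample_sheath_counts(p, 10.0, 5000, rng, primed=True)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 3.5) < 3 * se

    def test_matches_master_equation_transient(self, rng):
        """SSA histogram vs master-equation pmf at a transient time."""
        p = K.KineticParams(1.0, 0.0, 0.0, 21.0, 6.0)
        t = 0.3
        counts = K.sample_sheath_counts(p, t, 5000, rng, primed=True)
        pmf = K.transient_pmf(p, t, init="zero")
        observed = np.bincount(counts, minlength=pmf.size).astype(float)
        expected = 5000 * pmf
        obs, exp = K._pool_expected(observed, expected)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        pval = stats.chi2.sf(chi2, obs.size - 1)
        assert pval > 0.001

    def test_deterministic_given_rng(self, wt_kinetics):
        a = K.sample_sheath_counts(wt_kinetics, 2.0, 100, np.random.default_rng(5))
        b = K.sample_sheath_counts(wt_kinetics, 2.0, 100, np.random.default_rng(5))
        assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# Master equation


class TestTransientPmf:
    def test_point_mass_with_nothing_active(self):
        p = K.KineticParams(0.0, 10.0, 1.0, 21.0, 6.0)
        pmf = K.transient_pmf(p, 0.0)
        assert pmf[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("t", [0.1, 0.5, 2.0, 8.0])
    def test_probability_conserved(self, t, wt_kinetics):
        pmf = K.transient_pmf(wt_kinetics, t)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(pmf >= 0)

    @pytest.mark.parametrize("t", [0.05, 0.2, 1.0, 3.0])
    def test_mean_matches_immigration_death_closed_form(self, t):
        p = K.KineticParams(1.0, 0.0, 0.0, 21.0, 6.0)
        pmf = K.transient_pmf(p, t, init="zero")
        mean = float(np.arange(pmf.size) @ pmf)
        assert mean == pytest.approx(K.transient_mean_all_active(p, t), abs=1e-6)

    def test_converges_to_poisson(self):
        p = K.KineticParams(1.0, 0.0, 0.0, 21.0, 6.0)
        pmf = K.transient_pmf(p, 20.0, init="zero")
        target = stats.poisson.pmf(np.arange(pmf.size), 3.5)
        assert 0.5 * np.abs(pmf - target).sum() < 1e-6

    def test_truncation_error_signalled(self):
        p = K.KineticParams(1.0, 0.0, 0.0, 21.0, 6.0)
        with pytest.raises(K.TruncationError):
            K.transient_pmf(p, 5.0, n_max=3)


# ---------------------------------------------------------------------------
# Fitting


class TestFitActivationCurve:
    def test_exact_recovery_on_noiseless_data(self, es401_fit_params):
        times = np.arange(0.5, 3.01, 0.5)
        series = K.ActivationSeries(
            times, K.activation_probability(es401_fit_params, times)
        )
        fit = K.fit_activation_curve(series)
        assert fit.p0 == pytest.approx(0.10, abs=1e-4)
        assert fit.tau_plus == pytest.approx(1.34, abs=1e-4)
        assert fit.lambda_plus == pytest.approx(0.118, abs=1e-4)
        assert fit.rss < 1e-10

    def test_flat_series_gives_zero_rate(self):
        times = np.arange(0.5, 3.01, 0.5)
        fit = K.fit_activation_curve(K.ActivationSeries(times, np.full(6, 0.10)))
        assert fit.p0 == pytest.approx(0.10)
        assert fit.lambda_plus == pytest.approx(0.0, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_requires_four_points(self):
        with pytest.raises(ValueError):
            K.fit_activation_curve(
                K.ActivationSeries(np.array([0.5, 1.0, 1.5]), np.array([0.1] * 3))
            )

    def test_recovery_under_counting_noise(self, es401_fit_params, rng):
        """Median recovered rate within 20% at the experimental cell count."""
        from t6sim.fixtures import make_activation_series

        times = np.arange(0.5, 3.01, 0.5)
        estimates = []
        for _ in range(200):
            series = make_activation_series(es401_fit_params, times, 680, rng)
            estimates.append(K.fit_activation_curve(series).lambda_plus)
        median = float(np.median(estimates))
        assert abs(median - 0.118) / 0.118 < 0.20


class TestFitExponentialDecay:
    def test_exact_log_linear_recovery(self):
        t = np.array([2.0, 3.0, 4.0, 5.0])
        fit = K.fit_exponential_decay(t, 100 * np.exp(-1.6 * t))
        assert fit.b == pytest.approx(1.6, abs=1e-6)
        assert fit.a == pytest.approx(100.0, rel=1e-6)

    def test_constant_counts_give_zero_rate(self):
        fit = K.fit_exponential_decay([2, 3, 4, 5], [40.0] * 4)
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    def test_early_points_excluded(self):
        t_all = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        counts = 100 * np.exp(-1.6 * t_all)
        counts[:2] = [500.0, 90.0]  # off-model early transient
        full = K.fit_exponential_decay(t_all, counts)
        late = K.fit_exponential_decay(t_all[2:], counts[2:])
        assert full == late

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            K.fit_exponential_decay([2, 3, 4], [1.0, 0.0, 2.0])


# ---------------------------------------------------------------------------
# Histogram statistics


class TestPoissonGof:
    def test_calibrated_under_the_null(self, rng):
        fails = 0
        for _ in range(200):
            hist = K.SheathHistogram.from_samples(rng.poisson(3.5, 5000))
            _, p = K.poisson_gof_test(hist)
            fails += p <= 0.001
        assert fails <= 2  # >= 99% of null draws accepted

    def test_gross_misfit_rejected(self):
        counts = np.zeros(8, dtype=int)
        counts[0] = counts[7] = 500  # mean 3.5 but bimodal
        _, p = K.poisson_gof_test(K.SheathHistogram(counts))
        assert p < 0.001

    def test_near_perfect_fit_has_small_statistic(self):
        expected = 2000 * stats.poisson.pmf(np.arange(12), 3.5)
        hist = K.SheathHistogram(np.round(expected).astype(int))
        chi2, p = K.poisson_gof_test(hist)
        assert chi2 < 2.0 and p > 0.5

    def test_small_or_degenerate_inputs(self):
        with pytest.raises(ValueError):
            K.poisson_gof_test(K.SheathHistogram(np.array([5, 3])))
        with pytest.raises(K.DegenerateDataError):
            K.poisson_gof_test(K.SheathHistogram(np.array([50])))


class TestTwoSampleChi2:
    def test_identical_histograms(self):
        h = K.SheathHistogram(np.array([10, 20, 15, 5]))
        chi2, p = K.two_sample_chi2(h, h)
        assert chi2 == 0.0 and p == 1.0

    def test_same_law_rarely_rejected(self, rng):
        fails = 0
        for _ in range(200):
            a = K.SheathHistogram.from_samples(rng.poisson(3.5, 2000))
            b = K.SheathHistogram.from_samples(rng.poisson(3.5, 2000))
            _, p = K.two_sample_chi2(a, b)
            fails += p <= 0.001
        assert fails <= 2

    def test_power_at_separated_means(self, rng):
        rejections = 0
        for _ in range(60):
            a = K.SheathHistogram.from_samples(rng.poisson(2.8, 3000))
            b = K.SheathHistogram.from_samples(rng.poisson(3.9, 3000))
            _, p = K.two_sample_chi2(a, b)
            rejections += p < 0.001
        assert rejections >= 57  # >= 95% power

    def test_small_samples_rejected(self):
        h = K.SheathHistogram(np.array([3, 4, 5]))
        with pytest.raises(ValueError):
            K.two_sample_chi2(h, h)


# ---------------------------------------------------------------------------
# CSV round-trips


def test_series_and_histogram_csv_round_trip(tmp_path, es401_fit_params, rng):
    from t6sim.fixtures import make_activation_series, make_sheath_histogram

    series = make_activation_series(es401_fit_params, [0.5, 1.0, 1.5, 2.0], 680, rng)
    series.to_csv(tmp_path / "series.csv")
    back = K.ActivationSeries.from_csv(tmp_path / "series.csv")
    assert np.array_equal(series.times, back.times)
    assert np.array_equal(series.fractions, back.fractions)
    assert np.array_equal(series.n_observed, back.n_observed)

    p = K.KineticParams(1.0, 0.0, 0.0, 21.0, 6.0)
    hist = make_sheath_histogram(p, 2.0, 500, rng, primed=True)
    hist.to_csv(tmp_path / "hist.csv")
    back = K.SheathHistogram.from_csv(tmp_path / "hist.csv")
    assert np.array_equal(hist.counts, back.counts)
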