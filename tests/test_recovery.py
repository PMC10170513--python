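"""Residence-time estimators: acceleration factor, t_META-D, replica stats."""

import numpy as np
import pytest
from scipy import stats

import metadrt as m
from metadrt.recovery import InvalidInputError, PS_PER_MINUTE, significance_stars


def synthetic_traj(v_values, unbound_last=True):
    n = len(v_values)
    unbound = np.zeros(n, dtype=bool)
    if unbound_last and n:
        unbound[-1] = True
    return m.MetaDTrajectory(
        times=np.arange(1.0, n + 1.0),
        cvs=np.zeros((n, 1)),
        bias_before=np.asarray(v_values, float),
        heights=np.full(n, 0.4),
        unbound=unbound,
        status="unbound" if unbound_last else "max_time_reached",
    )


class TestAccelerationFactor:
    def test_null_bias_gives_unity(self):
        series = m.acceleration_factor(synthetic_traj(np.zeros(50)), beta=1.67)
        assert np.allclose(series.alpha, 1.0)

    def test_constant_bias_closed_form(self):
        beta, c = 1.67, 2.0
        series = m.acceleration_factor(synthetic_traj(np.full(20, c)), beta)
        assert np.allclose(series.alpha, np.exp(beta * c))

    @pytest.mark.parametrize("k", [10, 100])
    def test_linear_ramp_geometric_series(self, k):
        """V_j = j·δ: running mean of e^{βδj} is a geometric sum."""
        beta, delta = 1.67, 0.05
        v = delta * np.arange(k + 1)
        series = m.acceleration_factor(synthetic_traj(v), beta)
        q = np.exp(beta * delta)
        expected = (q ** (k + 1) - 1) / ((q - 1) * (k + 1))
        assert series.alpha[k] == pytest.approx(expected, rel=1e-10)

    def test_overflow_safe_log_accumulation(self):
        """β·V of several hundred stays finite in log space."""
        beta = 1.67
        v = np.linspace(0, 500, 100)
        series = m.acceleration_factor(synthetic_traj(v), beta)
        assert np.all(np.isfinite(series.log_alpha))
        assert series.log_alpha[-1] > 600  # e^600-scale alpha, as log

    def test_alpha_monotone_under_monotone_bias(self):
        v = np.linspace(0, 3, 200)
        series = m.acceleration_factor(synthetic_traj(v), beta=1.67)
        assert np.all(np.diff(series.log_alpha) >= -1e-12)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(InvalidInputError):
            m.acceleration_factor(synthetic_traj([]), beta=1.0)


class TestTransitionTime:
    def make_series(self, alphas):
        log_a = np.log(alphas)
        return m.AlphaSeries(
            times=np.arange(1.0, len(alphas) + 1.0),
            alpha=np.asarray(alphas, float),
            log_alpha=log_a,
            bound_mask=np.ones(len(alphas), bool),
        )

    def test_strictly_increasing_is_unconverged(self):
        t, a, conv = m.transition_time(self.make_series([1, 2, 3, 4]))
        assert (t, a, conv) == (4.0, 4.0, False)

    def test_interior_peak_detected(self):
        alphas = np.concatenate([np.linspace(1, 50, 50), np.linspace(49, 20, 30)])
        t, a, conv = m.transition_time(self.make_series(alphas))
        assert t == 50.0 and a == 50.0 and conv

    def test_tied_maxima_take_earliest(self):
        t, a, conv = m.transition_time(self.make_series([1, 5, 3, 5, 2]))
        assert t == 2.0 and conv


class TestRTCalcd:
    def test_unbiased_limit_recovers_transition_time(self):
        est = m.rt_calcd(1.0, 123.0)
        assert est.rt_calcd_ps == pytest.approx(123.0)

    def test_product_arithmetic(self):
        est = m.rt_calcd(1e6, 100.0)
        assert est.rt_calcd_ps == pytest.approx(1e8)
        assert est.rt_calcd_minutes == pytest.approx(1e8 / PS_PER_MINUTE)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            m.rt_calcd(0.5, 10.0)
        with pytest.raises(InvalidInputError):
            m.rt_calcd(2.0, 0.0)

    def test_zero_bias_run_yields_rt_equal_tstar(self):
        """End-to-end unbiased limit: V ≡ 0 ⇒ α ≡ 1 ⇒ RT = t*."""
        traj = synthetic_traj(np.zeros(30))
        est = m.flooding_estimate(traj, beta=1.67)
        assert est.alpha_max == pytest.approx(1.0, rel=1e-12)
        assert est.rt_calcd_ps == pytest.approx(est.t_transition)


class TestTMetad:
    def test_unbound_at_first_record(self):
        traj = synthetic_traj([0.0])
        res = m.t_metad(traj)
        assert res.t_metad_ps == 1.0 and not res.censored

    def test_never_unbound_is_censored(self):
        traj = synthetic_traj(np.zeros(10), unbound_last=False)
        assert m.t_metad(traj).censored

    def test_matches_frame_rescan_on_funnel(self):
        """First-unbound time equals a frame-by-frame rescan of the record."""
        system = m.build_system({"kind": "funnel2d", "barrier_kt": 5.0})
        traj = m.run_metad(
            system,
            m.TMETAD_PARAMS,
            m.DepositionSchedule(stride=1.0, max_time=500.0),
            seed=17,
        )
        assert traj.status == "unbound"
        res = m.t_metad(traj)
        rescan = [t for t, s in zip(traj.times, traj.cvs) if s[0] >= system.unbound_at]
        assert res.t_metad_ps == rescan[0]


class TestAggregation:
    def test_equal_values(self):
        s = m.aggregate_replicas([7.0] * 5)
        assert s.tau == pytest.approx(7.0)
        assert s.sem == pytest.approx(0.0)

    def test_two_decades_geometric_mean(self):
        s = m.aggregate_replicas([10.0, 1000.0])
        assert s.log_mean == pytest.approx(2.0)
        assert s.tau == pytest.approx(100.0)

    def test_single_value_sem_undefined(self):
        s = m.aggregate_replicas([42.0])
        assert np.isnan(s.sem)

    def test_lognormal_median_recovery(self):
        rng = np.random.default_rng(12)
        median = 50.0
        draws = np.exp(np.log(median) + 0.8 * rng.standard_normal(10))
        s = m.aggregate_replicas(draws)
        assert abs(s.log_mean - np.log10(median)) < 3 * s.sem

    def test_non_positive_rejected(self):
        with pytest.raises(InvalidInputError):
            m.aggregate_replicas([1.0, -2.0])


class TestECDAndPoisson:
    def test_single_value(self):
        curve = m.ecd([3.3])
        assert curve.values.tolist() == [3.3]
        assert curve.probabilities.tolist() == [1.0]

    def test_quartiles(self):
        curve = m.ecd([3, 1, 4, 2])
        assert curve.values.tolist() == [1, 2, 3, 4]
        assert curve.probabilities.tolist() == [0.25, 0.5, 0.75, 1.0]

    def test_duplicates_step_height(self):
        curve = m.ecd([2.0, 2.0, 5.0, 1.0])
        assert np.count_nonzero(curve.values == 2.0) == 2

    def test_poisson_cdf_limits(self):
        assert m.poisson_cdf(0.0, theta=3.0) == 0.0
        assert m.poisson_cdf(3.0 * np.log(2), theta=3.0) == pytest.approx(0.5)
        assert m.poisson_cdf(1e6, theta=3.0) == pytest.approx(1.0)

    def test_poisson_modes_are_parameterisations(self):
        # as_printed applies the same formula to log-scale inputs
        assert m.poisson_cdf(2.0, 2.0, mode="as_printed") == m.poisson_cdf(2.0, 2.0)
        with pytest.raises(ValueError):
            m.poisson_cdf(1.0, 1.0, mode="bogus")


class TestExponentialityCheck:
    def test_exact_exponential_quantiles_fit(self):
        q = -np.log(1 - (np.arange(1, 41) - 0.5) / 40)  # exponential quantiles
        stat, p = m.exponentiality_check(q)
        assert stat < 0.1 and p > 0.9

    def test_degenerate_constant_sample_rejected(self):
        stat, p = m.exponentiality_check([5.0] * 20)
        assert stat > 0.5 and p < 0.01

    def test_rejection_rate_conservative_under_null(self):
        """With the rate fitted from the data, the KS test rejects less
        often than nominal — checked over 200 seeded exponential samples."""
        rng = np.random.default_rng(100)
        rejections = sum(
            m.exponentiality_check(rng.exponential(scale=3.0, size=1000))[1] < 0.05
            for _ in range(200)
        )
        assert rejections / 200 <= 0.05


class TestTTest:
    def test_identical_samples(self):
        t, dof, p, stars = m.unpaired_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0 and stars == "ns"

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 3.5], [4.0, 5.5, 7.0]
        t1, _, p1, _ = m.unpaired_t_test(a, b)
        t2, _, p2, _ = m.unpaired_t_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_hand_computed_case(self):
        """a = {1,2,3}, b = {2,4,6}: pooled s² = 2.5, t = −2/√(5/3)."""
        t, dof, p, _ = m.unpaired_t_test([1, 2, 3], [2, 4, 6])
        t_expected = -2.0 / np.sqrt(2.5 * (2.0 / 3.0))
        assert t == pytest.approx(t_expected, abs=1e-10)
        assert dof == 4
        assert p == pytest.approx(2 * stats.t.sf(abs(t_expected), 4), abs=1e-10)

    def test_zero_variance_unequal_means(self):
        t, _, p, stars = m.unpaired_t_test([1, 1], [2, 2])
        assert np.isinf(t) and p == 0.0 and stars == "***"

    def test_star_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"
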