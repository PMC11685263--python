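import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tmcsim import (
    BootstrapResult,
    MediationFit,
    ReplicationData,
    SimulationCondition,
    bootstrap_indirect,
    child_rng,
    detect,
    fit_paths,
    generate_replication,
    two_sample_t_test,
)
from tmcsim.errors import (
    CollinearityError,
    ConfigurationError,
    DegenerateDataError,
)


def _make_data(x, m, y):
    x = np.asarray(x, dtype=float)
    return ReplicationData(
        x=x, t=x, m=np.asarray(m, dtype=float), y=np.asarray(y, dtype=float),
        seed_record=(0,),
    )


class TestTTest:
    def test_hand_computed_pooled_t(self):
        # groups (0,1) vs (2,3): mean diff -2, pooled var 0.5, |t| = 2*sqrt(2)
        y = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        t_stat, p = two_sample_t_test(y, x)
        assert abs(t_stat) == pytest.approx(2.0 * np.sqrt(2.0), abs=1e-12)
        assert p == pytest.approx(2.0 * stats.t.sf(2.0 * np.sqrt(2.0), 2), abs=1e-12)

    def test_identical_groups_give_zero_statistic(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        x = np.repeat([-1.0, 1.0], 3)
        t_stat, p = two_sample_t_test(y, x)
        assert t_stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            two_sample_t_test(np.array([0.0, 0.0, 1.0, 1.0]),
                              np.array([-1.0, -1.0, 1.0, 1.0]))

    def test_small_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            two_sample_t_test(np.array([0.0, 1.0, 2.0]),
                              np.array([-1.0, 1.0, 1.0]))

    def test_equals_regression_slope_test(self, replication):
        # balanced effect coding: pooled t-test == slope test of Y ~ X
        _, p = two_sample_t_test(replication.y, replication.x)
        fit = fit_paths(replication)
        assert p == pytest.approx(fit.p_c, abs=1e-12)
        assert fit.t_test_p == pytest.approx(fit.p_c, abs=1e-12)


class TestFitPaths:
    def test_orthogonal_hand_case(self):
        # X and M orthogonal, Y = M exactly: pure mediator effect
        x = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        m = np.array([1.0, 0.0, -1.0, 1.0, 0.0, -1.0])
        fit = fit_paths(_make_data(x, m, m))
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert fit.b == pytest.approx(1.0, abs=1e-12)
        assert fit.c == pytest.approx(0.0, abs=1e-12)
        assert fit.c_prime == pytest.approx(0.0, abs=1e-12)
        assert fit.ab == pytest.approx(0.0, abs=1e-12)
        assert fit.vif == pytest.approx(1.0, abs=1e-12)

    def test_perfect_collinearity_rejected(self):
        x = np.repeat([-1.0, 1.0], 5)
        with pytest.raises(CollinearityError):
            fit_paths(_make_data(x, x, np.arange(10.0)))

    def test_matches_statsmodels(self, replication):
        sm = pytest.importorskip("statsmodels.api")
        design2 = sm.add_constant(
            np.column_stack([replication.x, replication.m]))
        full = sm.OLS(replication.y, design2).fit()
        amod = sm.OLS(replication.m, sm.add_constant(replication.x)).fit()
        total = sm.OLS(replication.y, sm.add_constant(replication.x)).fit()
        fit = fit_paths(replication)
        assert fit.a == pytest.approx(amod.params[1], abs=1e-10)
        assert fit.se_a == pytest.approx(amod.bse[1], abs=1e-10)
        assert fit.p_a == pytest.approx(amod.pvalues[1], abs=1e-10)
        assert fit.c == pytest.approx(total.params[1], abs=1e-10)
        assert fit.se_c == pytest.approx(total.bse[1], abs=1e-10)
        assert fit.c_prime == pytest.approx(full.params[1], abs=1e-10)
        assert fit.b == pytest.approx(full.params[2], abs=1e-10)
        assert fit.se_b == pytest.approx(full.bse[2], abs=1e-10)
        assert fit.p_b == pytest.approx(full.pvalues[2], abs=1e-10)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_total_effect_decomposition(self, seed):
        # exact OLS identity c = a*b + c' on any dataset
        c = SimulationCondition(0.7, 0.7, 0.3, 0.5, n_per_group=10)
        data = generate_replication(c, seed)
        fit = fit_paths(data)
        assert fit.c == pytest.approx(fit.ab + fit.c_prime, abs=1e-10)
        assert fit.vif >= 1.0

    def test_sign_equivariance_under_group_relabeling(self, replication):
        flipped = ReplicationData(
            x=-replication.x, t=replication.t, m=replication.m,
            y=replication.y, seed_record=replication.seed_record,
        )
        f1 = fit_paths(replication)
        f2 = fit_paths(flipped)
        assert f2.a == pytest.approx(-f1.a, abs=1e-12)
        assert f2.c == pytest.approx(-f1.c, abs=1e-12)
        assert f2.c_prime == pytest.approx(-f1.c_prime, abs=1e-12)
        assert f2.b == pytest.approx(f1.b, abs=1e-12)
        assert f2.ab == pytest.approx(-f1.ab, abs=1e-12)
        # two-sided tests: detection is label-invariant
        b1 = bootstrap_indirect(replication, n_boot=200, rng=9)
        b2 = bootstrap_indirect(flipped, n_boot=200, rng=9)
        assert b2.ci_lower == pytest.approx(-b1.ci_upper, abs=1e-12)
        assert b1.significant == b2.significant
        for rule in ("baron_kenny", "bootstrap"):
            assert detect(f1, b1, rule=rule) == detect(f2, b2, rule=rule)


class TestBootstrap:
    def test_constant_outcome_gives_degenerate_interval(self):
        x = np.repeat([-1.0, 1.0], 10)
        rng = np.random.default_rng(0)
        data = _make_data(x, rng.standard_normal(20), np.ones(20))
        res = bootstrap_indirect(data, n_boot=100, rng=1)
        assert res.ci_lower == res.ci_upper == 0.0
        assert not res.significant

    def test_matches_per_resample_ols(self, replication):
        # dual route: vectorized moment algebra vs plain per-resample OLS
        n_boot = 20
        res = bootstrap_indirect(replication, n_boot=n_boot, rng=123)
        rng = np.random.default_rng(123)
        idx = rng.integers(0, replication.n, size=(n_boot, replication.n))
        expected = []
        for row in idx:
            x, m, y = replication.x[row], replication.m[row], replication.y[row]
            a = np.polyfit(x, m, 1)[0]
            design = np.column_stack([np.ones(row.size), x, m])
            b = np.linalg.lstsq(design, y, rcond=None)[0][2]
            expected.append(a * b)
        assert res.ab_samples == pytest.approx(np.asarray(expected), abs=1e-10)

    def test_percentile_convention_is_linear_interpolation(self, replication):
        res = bootstrap_indirect(replication, n_boot=20, alpha=0.05, rng=5)
        s = np.sort(res.ab_samples)

        def quantile(q):
            pos = q * (s.size - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            hi = min(lo + 1, s.size - 1)
            return s[lo] + frac * (s[hi] - s[lo])

        assert res.ci_lower == pytest.approx(quantile(0.025), abs=1e-12)
        assert res.ci_upper == pytest.approx(quantile(0.975), abs=1e-12)
        assert res.ci_lower <= res.ci_upper
        assert res.n_boot == 20

    def test_significance_is_zero_exclusion(self, replication):
        res = bootstrap_indirect(replication, n_boot=500, rng=2)
        assert res.significant == (res.ci_lower > 0 or res.ci_upper < 0)

    def test_reproducible_given_rng_seed(self, replication):
        r1 = bootstrap_indirect(replication, n_boot=50, rng=7)
        r2 = bootstrap_indirect(replication, n_boot=50, rng=7)
        assert np.array_equal(r1.ab_samples, r2.ab_samples)

    def test_invalid_arguments_rejected(self, replication):
        with pytest.raises(ConfigurationError):
            bootstrap_indirect(replication, n_boot=0)
        with pytest.raises(ConfigurationError):
            bootstrap_indirect(replication, alpha=1.5)


class TestDetect:
    @staticmethod
    def _fit(t_test_p, p_a, p_b):
        return MediationFit(
            a=0.5, se_a=0.1, p_a=p_a, b=0.5, se_b=0.1, p_b=p_b,
            c=0.5, se_c=0.1, p_c=0.01, c_prime=0.25, se_c_prime=0.1,
            p_c_prime=0.1, ab=0.25, t_test_p=t_test_p, vif=1.2,
        )

    @staticmethod
    def _boot(lo, hi):
        return BootstrapResult(
            ci_lower=lo, ci_upper=hi, n_boot=100,
            significant=(lo > 0 or hi < 0), ab_samples=np.empty(0),
        )

    def test_overall_effect_required_by_both_rules(self):
        fit = self._fit(t_test_p=0.20, p_a=0.001, p_b=0.001)
        boot = self._boot(0.2, 0.4)
        assert not detect(fit, boot, rule="baron_kenny")
        assert not detect(fit, boot, rule="bootstrap")

    def test_all_significant_detected_by_both_rules(self):
        fit = self._fit(t_test_p=0.0, p_a=0.0, p_b=0.0)
        boot = self._boot(0.2, 0.4)
        assert detect(fit, boot, rule="baron_kenny")
        assert detect(fit, boot, rule="bootstrap")

    def test_failed_b_path_and_straddling_interval(self):
        fit = self._fit(t_test_p=0.001, p_a=0.001, p_b=0.40)
        boot = self._boot(-0.1, 0.3)
        assert not detect(fit, boot, rule="baron_kenny")
        assert not detect(fit, boot, rule="bootstrap")

    def test_unknown_rule_rejected(self):
        fit = self._fit(0.01, 0.01, 0.01)
        with pytest.raises(ConfigurationError):
            detect(fit, self._boot(0.1, 0.2), rule="sobel")
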