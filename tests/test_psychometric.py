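"""Sigmoid/flip evaluation, maximum-likelihood fitting, GoF and reversal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import tojcortex as tc
from tojcortex.psychometric import JudgmentTable, goodness_of_fit

SOA_GRID = np.linspace(-900, 900, 181)


def unit_interval(**kw):
    return st.floats(0.0, 1.0, allow_nan=False, **kw)


flip_params = st.builds(
    tc.FlipParams,
    a_l=unit_interval(),
    a_r=unit_interval(),
    sigma_f=st.floats(1.0, 1000.0),
    d=st.floats(-500.0, 500.0),
    c=unit_interval(),
)


@st.composite
def sigmoid_params(draw):
    lo = draw(unit_interval())
    hi = draw(st.floats(lo, 1.0))
    return tc.SigmoidParams(
        p_max=hi, p_min=lo, sigma_u=draw(st.floats(1.0, 500.0)), d_u=draw(st.floats(-300.0, 300.0))
    )


class TestEvaluate:
    def test_sigmoid_midpoint_and_asymptotes(self):
        params = tc.SigmoidParams(1.0, 0.0, 50.0, 0.0)
        assert tc.evaluate_sigmoid(params, 0.0) == pytest.approx(0.5)
        # one sd above the midpoint: standard normal CDF at 1
        assert tc.evaluate_sigmoid(params, 50.0) == pytest.approx(
            stats.norm.cdf(1.0), abs=1e-10
        )
        limited = tc.SigmoidParams(0.9, 0.1, 50.0, 0.0)
        assert tc.evaluate_sigmoid(limited, 1e7) == pytest.approx(0.9)
        assert tc.evaluate_sigmoid(limited, -1e7) == pytest.approx(0.1)

    def test_sigmoid_monotone_nondecreasing(self):
        params = tc.SigmoidParams(0.95, 0.05, 80.0, -20.0)
        p = tc.evaluate_sigmoid(params, SOA_GRID)
        assert np.all(np.diff(p) >= 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            tc.SigmoidParams(0.5, 0.9, 50.0, 0.0)  # p_min > p_max
        with pytest.raises(ValueError):
            tc.SigmoidParams(1.0, 0.0, -5.0, 0.0)
        with pytest.raises(ValueError):
            tc.FlipParams(1.2, 0.0, 100.0, 0.0, 0.0)

    @given(sigmoid=sigmoid_params())
    def test_zero_flip_is_identity(self, sigmoid):
        flip = tc.FlipParams(0.0, 0.0, 100.0, 0.0, 0.0)
        np.testing.assert_allclose(
            tc.evaluate_flip(flip, sigmoid, SOA_GRID),
            tc.evaluate_sigmoid(sigmoid, SOA_GRID),
            atol=1e-12,
        )

    def test_unit_constant_flip_inverts(self):
        sigmoid = tc.SigmoidParams(1.0, 0.0, 50.0, 0.0)
        flip = tc.FlipParams(0.0, 0.0, 100.0, 0.0, 1.0)
        np.testing.assert_allclose(
            tc.evaluate_flip(flip, sigmoid, SOA_GRID),
            1.0 - np.asarray(tc.evaluate_sigmoid(sigmoid, SOA_GRID)),
            atol=1e-12,
        )

    def test_full_peak_flip_at_centre(self):
        sigmoid = tc.SigmoidParams(0.9, 0.1, 50.0, 10.0)
        flip = tc.FlipParams(1.0, 1.0, 100.0, 0.0, 0.0)
        p_u0 = tc.evaluate_sigmoid(sigmoid, 0.0)
        assert tc.evaluate_flip(flip, sigmoid, 0.0) == pytest.approx(1.0 - p_u0)

    @given(flip=flip_params, sigmoid=sigmoid_params())
    def test_flip_output_is_probability(self, flip, sigmoid):
        p = np.asarray(tc.evaluate_flip(flip, sigmoid, SOA_GRID))
        assert np.all((p >= 0) & (p <= 1))


class TestTabulate:
    def test_direct_count(self):
        trials = pd.DataFrame(
            {
                "soa_ms": [100.0] * 8,
                "is_catch": [False] * 8,
                "response_left_second": [1, 1, 1, 1, 1, 0, 0, 0],
            }
        )
        table = tc.tabulate_judgments(trials)
        assert table.soa_ms.tolist() == [100.0]
        assert table.n_trials.tolist() == [8]
        assert table.n_left_second.tolist() == [5]

    def test_only_catch_trials_rejected(self):
        trials = pd.DataFrame(
            {"soa_ms": [100.0], "is_catch": [True], "response_left_second": [1]}
        )
        with pytest.raises(ValueError):
            tc.tabulate_judgments(trials)

    def test_full_crossed_session(self, session_pair):
        _, crossed = session_pair
        table = tc.tabulate_judgments(crossed)
        assert table.n_levels == 14
        assert table.n_trials.sum() == 112  # catch trials excluded from 128


def simulate_table(sigmoid, flip, levels, reps, seed, crossed):
    rng = np.random.default_rng(seed)
    soa = np.asarray(levels)
    p = (
        np.asarray(tc.evaluate_flip(flip, sigmoid, soa))
        if crossed
        else np.asarray(tc.evaluate_sigmoid(sigmoid, soa))
    )
    k = rng.binomial(reps, p)
    return JudgmentTable(soa_ms=soa, n_trials=np.full(soa.size, reps), n_left_second=k)


class TestFitting:
    def test_step_data_recovers_asymptotes(self):
        soa = np.asarray(tc.synthetic.UNCROSSED_LEVELS)
        table = JudgmentTable(
            soa_ms=soa,
            n_trials=np.full(12, 8),
            n_left_second=np.where(soa > 0, 8, 0),
        )
        fit = tc.fit_uncrossed(table, seed=0)
        assert fit.params.p_max >= 0.99
        assert fit.params.p_min <= 0.01

    def test_loglik_at_least_generating_value(self, fitted_pair, session_pair, ground_truth_subject):
        """The MLE log-likelihood can never fall below the truth's."""
        u_fit, c_fit = fitted_pair
        uncrossed, crossed = session_pair
        sub = ground_truth_subject
        tab_u = tc.tabulate_judgments(uncrossed)
        tab_c = tc.tabulate_judgments(crossed)

        def loglik(p, tab):
            p = np.clip(p, 1e-6, 1 - 1e-6)
            return float(
                np.sum(
                    tab.n_left_second * np.log(p)
                    + (tab.n_trials - tab.n_left_second) * np.log1p(-p)
                )
            )

        gen_u = loglik(np.asarray(tc.evaluate_sigmoid(sub.sigmoid, tab_u.soa_ms)), tab_u)
        gen_c = loglik(
            np.asarray(tc.evaluate_flip(sub.flip, u_fit.params, tab_c.soa_ms)), tab_c
        )
        assert u_fit.loglik >= gen_u - 1e-9
        assert c_fit.loglik >= gen_c - 1e-9

    def test_full_inversion_recovered(self):
        sigmoid = tc.SigmoidParams(0.99, 0.01, 50.0, 0.0)
        flip = tc.FlipParams(0.0, 0.0, 150.0, 0.0, 1.0)
        tab_u = simulate_table(sigmoid, None, tc.synthetic.UNCROSSED_LEVELS, 400, 1, False)
        tab_c = simulate_table(sigmoid, flip, tc.synthetic.CROSSED_LEVELS, 400, 2, True)
        u_fit = tc.fit_uncrossed(tab_u, seed=3)
        c_fit = tc.fit_crossed(tab_c, u_fit, seed=4)
        assert c_fit.params.c >= 0.9

    def test_no_reversal_recovered(self):
        sigmoid = tc.SigmoidParams(0.99, 0.01, 50.0, 0.0)
        flip = tc.FlipParams(0.0, 0.0, 150.0, 0.0, 0.0)
        tab_u = simulate_table(sigmoid, None, tc.synthetic.UNCROSSED_LEVELS, 400, 5, False)
        tab_c = simulate_table(sigmoid, flip, tc.synthetic.CROSSED_LEVELS, 400, 6, True)
        u_fit = tc.fit_uncrossed(tab_u, seed=7)
        c_fit = tc.fit_crossed(tab_c, u_fit, seed=8)
        summary = tc.reversal_summary(c_fit, u_fit)
        assert summary.reversal_value <= 0.05

    def test_too_few_levels_rejected(self):
        table = JudgmentTable(
            soa_ms=np.array([-100.0, -50.0, 0.0, 50.0, 100.0]),
            n_trials=np.full(5, 8),
            n_left_second=np.array([0, 1, 4, 7, 8]),
        )
        with pytest.raises(ValueError):
            tc.fit_uncrossed(table)


class TestGoodnessOfFit:
    def test_near_perfect_fit(self):
        """Observed frequencies matching the predictions give chi2 ~ 0, R^2 ~ 1."""
        sigmoid = tc.SigmoidParams(0.9, 0.1, 150.0, 0.0)  # p stays clear of 0/1
        soa = np.asarray(tc.synthetic.UNCROSSED_LEVELS)
        p = np.asarray(tc.evaluate_sigmoid(sigmoid, soa))
        n = np.full(12, 10**6)  # rounding error in k is then negligible
        k = np.round(n * p).astype(int)
        fit = tc.PsychFit(sigmoid, 0.0, 12, np.nan, 0, np.nan, np.nan, True)
        chi2, df, p_val, r2 = goodness_of_fit(fit, JudgmentTable(soa, n, k))
        assert df == 7
        assert chi2 == pytest.approx(0.0, abs=1e-2)
        assert r2 == pytest.approx(1.0, abs=1e-8)

    def test_degrees_of_freedom(self, fitted_pair):
        u_fit, c_fit = fitted_pair
        assert u_fit.df == 7  # 12 levels - 4 params - 1
        assert c_fit.df == 8  # 14 levels - 5 params - 1

    def test_chi2_matches_brute_force(self, fitted_pair, session_pair):
        u_fit, _ = fitted_pair
        table = tc.tabulate_judgments(session_pair[0])
        p = np.clip(
            np.asarray(tc.evaluate_sigmoid(u_fit.params, table.soa_ms)), 1e-6, 1 - 1e-6
        )
        manual = sum(
            (k - n * pi) ** 2 / (n * pi * (1 - pi))
            for k, n, pi in zip(table.n_left_second, table.n_trials, p)
        )
        assert u_fit.chi2 == pytest.approx(manual, abs=1e-12)


class TestChi2Critical:
    @pytest.mark.parametrize(
        "alpha, df, expected",
        [(0.05, 8, 15.5), (0.05, 7, 14.1), (0.05, 1, 3.84)],
    )
    def test_reference_values(self, alpha, df, expected):
        assert round(tc.chi2_critical(alpha, df), len(str(expected).split(".")[1])) == expected

    def test_monotone_in_df(self):
        values = [tc.chi2_critical(0.05, df) for df in range(1, 21)]
        assert np.all(np.diff(values) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tc.chi2_critical(0.0, 5)
        with pytest.raises(ValueError):
            tc.chi2_critical(0.05, 0)


class TestReversal:
    def test_identical_curves_zero(self):
        sigmoid = tc.SigmoidParams(0.95, 0.05, 60.0, 0.0)
        flip = tc.FlipParams(0.0, 0.0, 100.0, 0.0, 0.0)
        assert tc.reversal_summary(flip, sigmoid).reversal_value == 0.0

    def test_full_inversion_near_one(self):
        sigmoid = tc.SigmoidParams(1.0, 0.0, 1.0, 0.0)  # near-step sigmoid
        flip = tc.FlipParams(0.0, 0.0, 100.0, 0.0, 1.0)
        assert tc.reversal_summary(flip, sigmoid).reversal_value >= 0.99

    def test_mean_peak_flip(self):
        sigmoid = tc.SigmoidParams(1.0, 0.0, 50.0, 0.0)
        flip = tc.FlipParams(0.6, 0.4, 100.0, 0.0, 0.0)
        assert tc.reversal_summary(flip, sigmoid).mean_peak_flip == pytest.approx(0.5)

    def test_grid_refinement(self):
        sigmoid = tc.SigmoidParams(0.97, 0.03, 55.0, 10.0)
        flip = tc.FlipParams(0.5, 0.3, 180.0, -30.0, 0.15)
        coarse = tc.reversal_summary(flip, sigmoid, grid_step_ms=5.0).reversal_value
        fine = tc.reversal_summary(flip, sigmoid, grid_step_ms=0.1).reversal_value
        assert coarse == pytest.approx(fine, abs=1e-3)

    def test_invalid_grid_step(self):
        sigmoid = tc.SigmoidParams(1.0, 0.0, 50.0, 0.0)
        flip = tc.FlipParams(0.0, 0.0, 100.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            tc.reversal_summary(flip, sigmoid, grid_step_ms=10.0)

    @given(flip=flip_params, sigmoid=sigmoid_params())
    def test_bounded_in_unit_interval(self, flip, sigmoid):
        value = tc.reversal_summary(flip, sigmoid, grid_step_ms=5.0).reversal_value
        assert 0.0 <= value <= 1.0

    @pytest.mark.parametrize("param", ["a_l", "a_r", "sigma_f", "c"])
    def test_increases_with_each_flip_parameter(self, param):
        """Each flip parameter drives the reversal value up (sign-level
        reproduction of the parameter/reversal correlation profile)."""
        sigmoid = tc.SigmoidParams(0.98, 0.02, 50.0, 0.0)
        base = {"a_l": 0.3, "a_r": 0.3, "sigma_f": 150.0, "d": 0.0, "c": 0.2}
        sweep = np.linspace(50, 400, 8) if param == "sigma_f" else np.linspace(0.0, 0.8, 8)
        values = []
        for v in sweep:
            flip = tc.FlipParams(**{**base, param: v})
            values.append(tc.reversal_summary(flip, sigmoid, grid_step_ms=5.0).reversal_value)
        rho = stats.spearmanr(sweep, values).statistic
        assert rho > 0.9
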