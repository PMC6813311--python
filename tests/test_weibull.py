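import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ecxsys import (
    DegenerateDataError,
    DomainError,
    WeibullParams,
    weibull_evaluate,
    weibull_fit,
    weibull_inverse,
)

TOX = WeibullParams(b=1.256, c=0.0, d=1.0, e=2.877)
SYS = WeibullParams(b=3.476, c=0.0, d=0.299, e=0.152)


class TestParams:
    def test_validation(self):
        with pytest.raises(DomainError):
            WeibullParams(b=-1, c=0, d=1, e=1)
        with pytest.raises(DomainError):
            WeibullParams(b=1, c=0, d=1, e=0)
        with pytest.raises(DomainError):
            WeibullParams(b=1, c=0.5, d=0.2, e=1)


class TestEvaluate:
    def test_x_zero_gives_upper_limit(self):
        assert weibull_evaluate(TOX, 0.0) == 1.0
        assert weibull_evaluate(SYS, 0.0) == 0.299

    def test_inflection_value(self):
        p = WeibullParams(b=2.0, c=0.1, d=0.9, e=1.5)
        assert weibull_evaluate(p, 1.5) == pytest.approx(0.1 + 0.8 * np.exp(-1), rel=1e-12)

    def test_reference_toxicant_curve(self):
        assert weibull_evaluate(TOX, 2.877) == pytest.approx(np.exp(-1), rel=1e-12)
        grid = np.logspace(np.log10(0.001), np.log10(30), 200)
        vals = np.asarray(weibull_evaluate(TOX, grid))
        assert np.all(np.diff(vals) < 0)
        assert vals[0] < 1.0

    def test_negative_x_rejected(self):
        with pytest.raises(DomainError):
            weibull_evaluate(TOX, -0.5)


class TestInverse:
    def test_inflection_round_trip(self):
        y = 0.0 + (1.0 - 0.0) * np.exp(-1)
        assert weibull_inverse(TOX, y) == pytest.approx(2.877, rel=1e-12)

    def test_sys_curve_one_percent_level(self):
        x = weibull_inverse(SYS, 0.01 * SYS.d)
        assert x == pytest.approx(0.152 * np.exp(np.log(-np.log(0.01)) / 3.476), rel=1e-12)
        assert x == pytest.approx(0.236, abs=5e-4)

    def test_matches_numeric_inversion(self):
        for y in np.linspace(0.02, 0.98, 25):
            closed = weibull_inverse(TOX, y)
            numeric = brentq(lambda x: weibull_evaluate(TOX, x) - y, 1e-9, 1e6,
                             xtol=1e-14, rtol=1e-15)
            assert closed == pytest.approx(numeric, rel=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            weibull_inverse(TOX, 1.0)
        with pytest.raises(DomainError):
            weibull_inverse(SYS, 0.5)


@settings(max_examples=100, deadline=None)
@given(
    b=st.floats(min_value=0.2, max_value=10),
    e=st.floats(min_value=1e-3, max_value=1e3),
    frac=st.floats(min_value=1e-3, max_value=1 - 1e-3),
)
def test_inverse_round_trip_property(b, e, frac):
    params = WeibullParams(b=b, c=0.1, d=0.8, e=e)
    y = 0.1 + frac * 0.7
    assert weibull_evaluate(params, weibull_inverse(params, y)) == pytest.approx(y, abs=1e-10)


class TestFit:
    def test_noiseless_recovery(self):
        xs = np.array([0.0, 0.3, 1.0, 3.0, 10.0])
        ys = np.asarray(weibull_evaluate(TOX, xs))
        result = weibull_fit(xs, ys, fixed={"c": 0.0, "d": 1.0})
        assert result.converged
        assert result.params.b == pytest.approx(1.256, rel=1e-6)
        assert result.params.e == pytest.approx(2.877, rel=1e-6)
        assert result.residual_sum_of_squares < 1e-15

    def test_single_free_parameter_matches_algebraic_solution(self):
        # with b, c, d fixed the optimum must run through the data points,
        # i.e. e equals the closed-form value from the inverse relation
        xs = np.array([1.0, 1.0001])
        ys = np.asarray(weibull_evaluate(TOX, xs))
        result = weibull_fit(xs, ys, fixed={"b": 1.256, "c": 0.0, "d": 1.0})
        algebraic = xs[0] / np.exp(np.log(-np.log(ys[0])) / 1.256)
        assert result.params.e == pytest.approx(algebraic, rel=1e-8)

    def test_mean_recovery_under_gaussian_noise(self):
        xs = np.logspace(-2, 1.3, 100)
        truth = np.asarray(weibull_evaluate(TOX, xs))
        rng = np.random.default_rng(7)
        recovered = []
        for _ in range(200):
            ys = np.clip(truth + rng.normal(0.0, 0.02, xs.size), 0.0, 1.0)
            recovered.append(weibull_fit(xs, ys, fixed={"c": 0.0, "d": 1.0}).params.e)
        assert np.mean(recovered) == pytest.approx(2.877, rel=0.02)

    def test_reorder_invariance(self):
        xs = np.array([0.0, 0.3, 1.0, 3.0, 10.0])
        ys = np.asarray(weibull_evaluate(TOX, xs)) + 0.01 * np.sin(np.arange(5))
        a = weibull_fit(xs, ys, fixed={"c": 0.0, "d": 1.0})
        perm = np.array([3, 0, 4, 2, 1])
        b = weibull_fit(xs[perm], ys[perm], fixed={"c": 0.0, "d": 1.0})
        assert a.params.b == pytest.approx(b.params.b, rel=1e-9)
        assert a.params.e == pytest.approx(b.params.e, rel=1e-9)

    def test_three_free_parameters_recovered(self):
        xs = np.linspace(0.0, 0.6, 12)
        ys = np.asarray(weibull_evaluate(SYS, xs))
        result = weibull_fit(xs, ys, fixed={"c": 0.0})
        assert result.params.b == pytest.approx(3.476, rel=1e-5)
        assert result.params.d == pytest.approx(0.299, rel=1e-5)
        assert result.params.e == pytest.approx(0.152, rel=1e-5)

    def test_degenerate_data_rejected(self):
        xs = np.array([0.0, 1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            weibull_fit(xs, np.array([0.5, 0.5, 0.5]), fixed={"c": 0.0, "d": 1.0})

    def test_fixed_values_respected(self):
        xs = np.array([0.0, 0.3, 1.0, 3.0, 10.0])
        ys = np.asarray(weibull_evaluate(TOX, xs))
        result = weibull_fit(xs, ys, fixed={"c": 0.0, "d": 1.0})
        assert result.params.c == 0.0
        assert result.params.d == 1.0
        assert result.fixed_mask == {"c": 0.0, "d": 1.0}
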