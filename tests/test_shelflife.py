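"""Parabola-symmetry shelf-life construction and its algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phytoshelf import (
    QuadraticModel,
    classify_relation,
    estimate,
    extremum,
    roots,
    shelf_life_x,
    to_series,
)
from phytoshelf.exceptions import NoRealRootsError
from phytoshelf.fitting import POSITIVE_QUADRATIC, RelationClass


def _quad(a, b, c):
    return QuadraticModel(a=a, b=b, c=c, r_squared=1.0, n_points=6, sse=0.0, sst=1.0)


def _bisect_root(a, b, c, lo, hi, tol=1e-12):
    """Independent sign-change bisection oracle for a x^2 + b x + c = 0."""
    f = lambda x: a * x * x + b * x + c
    assert f(lo) * f(hi) < 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


PRINTED = _quad(-0.0594, 0.2275, 0.3876)


class TestWorkedExample:
    """The one fitted parabola the emulated study prints in full."""

    def test_extremum(self):
        assert extremum(PRINTED) == pytest.approx(1.9149, abs=1e-3)

    def test_roots_match_bisection_oracle(self):
        rn, rp = roots(PRINTED)
        oracle_n = _bisect_root(-0.0594, 0.2275, 0.3876, -10.0, 0.0)
        oracle_p = _bisect_root(-0.0594, 0.2275, 0.3876, 1.9149, 20.0)
        assert rn == pytest.approx(oracle_n, abs=1e-6)
        assert rp == pytest.approx(oracle_p, abs=1e-6)
        assert rn == pytest.approx(-1.2776, abs=1e-3)
        assert rp == pytest.approx(5.1076, abs=1e-3)

    def test_x3_and_antilog_weeks(self):
        x3 = shelf_life_x(PRINTED)
        assert x3 == pytest.approx(3.8300, abs=1e-3)
        assert 3.0**x3 == pytest.approx(67.2, abs=0.2)


class TestTrivialParabolas:
    @pytest.mark.parametrize("a, b, x2", [(-1.0, 0.0, 0.0), (-1.0, 2.0, 1.0)])
    def test_extremum(self, a, b, x2):
        assert extremum(_quad(a, b, 0.5)) == pytest.approx(x2)

    def test_symmetric_roots(self):
        assert roots(_quad(1.0, 0.0, -1.0)) == (pytest.approx(-1.0), pytest.approx(1.0))

    def test_negative_discriminant_raises(self):
        with pytest.raises(NoRealRootsError):
            roots(_quad(1.0, 0.0, 1.0))

    def test_x3_simple(self):
        assert shelf_life_x(_quad(-1.0, 2.0, 1.0)) == pytest.approx(2.0)

    def test_degenerate_a_zero(self):
        with pytest.raises(ValueError):
            extremum(_quad(0.0, 1.0, 1.0))


valid_quadratics = st.tuples(
    st.floats(min_value=-3.0, max_value=-0.05),
    st.floats(min_value=0.05, max_value=3.0),
    st.floats(min_value=0.01, max_value=3.0),
)


class TestIdentities:
    @given(valid_quadratics)
    def test_x3_equals_minus_b_over_a_and_twice_extremum(self, abc):
        a, b, c = abc
        m = _quad(a, b, c)
        x3 = shelf_life_x(m)
        assert x3 == pytest.approx(-b / a, abs=1e-9)
        assert x3 == pytest.approx(2.0 * extremum(m), abs=1e-9)
        rn, rp = roots(m)
        assert x3 == pytest.approx(rp + rn, abs=1e-9)  # sum of roots

    @given(valid_quadratics)
    def test_closure_concentration_returns_to_intercept(self, abc):
        a, b, c = abc
        m = _quad(a, b, c)
        x3 = shelf_life_x(m)
        assert m.predict(x3) == pytest.approx(c, abs=1e-6)

    @given(valid_quadratics, st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, abc, k):
        # scaling all concentrations by k scales (a, b, c) together and
        # leaves the time-side quantities unchanged
        a, b, c = abc
        m, mk = _quad(a, b, c), _quad(k * a, k * b, k * c)
        assert extremum(mk) == pytest.approx(extremum(m), rel=1e-9)
        assert shelf_life_x(mk) == pytest.approx(shelf_life_x(m), rel=1e-9)

    @given(valid_quadratics)
    def test_roots_match_bisection(self, abc):
        a, b, c = abc
        rn, rp = roots(_quad(a, b, c))
        assert a * rn * rn + b * rn + c == pytest.approx(0.0, abs=1e-9)
        oracle_p = _bisect_root(a, b, c, -b / (2 * a), rp + 1.0)
        assert rp == pytest.approx(oracle_p, abs=1e-6)


class TestEstimate:
    def _relation(self, label, model=None, x_max=5.0):
        return RelationClass(label=label, chosen_model=model, x_max=x_max)

    def test_positive_quadratic_full_estimate(self):
        sl = estimate(self._relation(POSITIVE_QUADRATIC, PRINTED))
        assert sl.predictable
        assert sl.shelf_life_weeks == pytest.approx(67.2, abs=0.2)
        assert sl.shelf_life_weeks_rounded == 67
        assert sl.y_at_x3 == pytest.approx(PRINTED.c, abs=1e-6)
        assert not sl.extrapolated  # x3 = 3.83 inside the 0..5 grid

    def test_negative_linear_not_predictable(self):
        sl = estimate(self._relation("negative_linear"))
        assert not sl.predictable
        assert "monotone decline" in sl.reason
        assert sl.shelf_life_weeks is None

    def test_flat_not_predictable(self):
        sl = estimate(self._relation("flat"))
        assert not sl.predictable

    def test_bad_coefficient_signs_routed_to_not_predictable(self):
        m = _quad(-0.1, 0.5, -0.2)  # c < 0: no positive intercept to return to
        sl = estimate(self._relation(POSITIVE_QUADRATIC, m))
        assert not sl.predictable

    def test_extrapolation_flag_on_cub_tropical(self, noise_free_samples):
        series = to_series(noise_free_samples, ("cuB", 52, "tropical"), "replicate_level")
        rel = classify_relation(series)
        sl = estimate(rel)
        assert sl.predictable
        assert sl.extrapolated
        assert sl.shelf_life_weeks == pytest.approx(825.0, abs=1.0)
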