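"""Cumulative-logistic probabilities, deviance, and E-step closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import expit

from ordmap import logistic
from ordmap.data import OrdinalDataset
from ordmap.logistic import (
    CURVATURE_BOUND,
    ThresholdError,
    category_probabilities,
    deviance,
    expected_gradient,
    working_responses,
)


class TestCategoryProbabilities:
    @pytest.mark.parametrize(
        "theta, tau, expected",
        [
            # symmetry of the logistic at zero (binary)
            (0.0, [0.0], [0.5, 0.5]),
            # high-precision evaluation of 1/(1+e^2) and 1/(1+e^0)
            (
                1.0,
                [-1.0, 1.0],
                [0.11920292202211755, 0.38079707797788245, 0.5],
            ),
        ],
    )
    def test_known_values(self, theta, tau, expected):
        p = category_probabilities(np.array([[theta]]), [np.array(tau)])
        np.testing.assert_allclose(p[0, 0, : len(expected)], expected, atol=1e-12)

    def test_extreme_theta_concentrates_on_first_category(self):
        p = category_probabilities(np.array([[-800.0]]), [np.array([-1.0, 1.0])])
        assert abs(p[0, 0, 0] - 1.0) < 1e-12
        assert p[0, 0, 1:].max() < 1e-12

    def test_rows_sum_to_one_and_cumulative_monotone(self, rng):
        theta = rng.normal(0, 3, (7, 4))
        tau = [np.sort(rng.normal(0, 2, c)) for c in (1, 2, 3, 4)]
        lam = logistic.cumulative_probabilities(theta, tau)
        p = category_probabilities(theta, tau)
        np.testing.assert_allclose(p.sum(axis=2), 1.0, atol=1e-12)
        assert (np.diff(lam, axis=2) >= -1e-15).all()
        assert (p >= -1e-15).all()

    def test_invalid_thresholds_raise(self):
        with pytest.raises(ThresholdError):
            category_probabilities(np.zeros((1, 1)), [np.array([1.0, -1.0])])

    @settings(max_examples=60, derandomize=True)
    @given(
        theta=st.floats(-700, 700),
        t1=st.floats(-50, 50),
        gap=st.floats(0.01, 20),
    )
    def test_probability_axioms_hold_everywhere(self, theta, t1, gap):
        """For any structural value and ordered thresholds the category
        probabilities are a proper distribution and the expected score lies
        in [-1, 1]."""
        tau = [np.array([t1, t1 + gap])]
        p = category_probabilities(np.array([[theta]]), tau)[0, 0]
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= -1e-15).all()
        for c in (1, 2, 3):
            y = OrdinalDataset(np.array([[c]]), [3])
            g = expected_gradient(y, np.array([[theta]]), tau)[0, 0]
            assert -1.0 <= g <= 1.0
            z = working_responses(np.array([[theta]]), np.array([[g]]))
            assert np.isfinite(z).all()


class TestDeviance:
    def test_uniform_four_categories(self):
        # thresholds at logit(1/4), logit(1/2), logit(3/4) make all four
        # categories equiprobable at theta = 0
        tau = [np.array([-np.log(3.0), 0.0, np.log(3.0)])] * 3
        y = OrdinalDataset((np.arange(24) % 4 + 1).reshape(8, 3), [4] * 3)
        dev = deviance(y, np.zeros((8, 3)), tau)
        assert dev == pytest.approx(2 * 8 * 3 * np.log(4.0), rel=1e-12)

    def test_single_cell_half_probability(self):
        y = OrdinalDataset(np.array([[1]]), [2])
        dev = deviance(y, np.zeros((1, 1)), [np.array([0.0])])
        assert dev == pytest.approx(2 * np.log(2.0), rel=1e-12)

    def test_matches_naive_per_cell_sum(self, rng):
        n, r = 10, 3
        theta = rng.normal(0, 2, (n, r))
        tau = [np.sort(rng.normal(0, 1.5, 2)) for _ in range(r)]
        y = OrdinalDataset(rng.integers(1, 4, (n, r)), [3] * r)
        # independent oracle: per-cell log of explicitly assembled categories
        total = 0.0
        for i in range(n):
            for j in range(r):
                t = np.concatenate(([-np.inf], tau[j], [np.inf]))
                c = y.y[i, j]
                p = expit(t[c] - theta[i, j]) - expit(t[c - 1] - theta[i, j])
                total += -2.0 * np.log(p)
        assert deviance(y, theta, tau) == pytest.approx(total, abs=1e-10)

    def test_row_permutation_equivariance(self, rng):
        theta = rng.normal(0, 1, (12, 2))
        tau = [np.array([-0.5, 0.7])] * 2
        y = rng.integers(1, 4, (12, 2))
        perm = rng.permutation(12)
        d1 = deviance(OrdinalDataset(y, [3, 3]), theta, tau)
        d2 = deviance(OrdinalDataset(y[perm], [3, 3]), theta[perm], tau)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_out_of_range_category_raises(self):
        with pytest.raises(ValueError):
            OrdinalDataset(np.array([[4]]), [3])


def _quadrature_expected_gradient(theta, tau, c):
    """Independent oracle: adaptive quadrature of the truncated-logistic
    expectation of the complete-data score."""
    full = np.concatenate(([-np.inf], np.atleast_1d(tau), [np.inf]))
    a, b = full[c - 1] - theta, full[c] - theta
    pdf = lambda x: expit(x) * (1 - expit(x))
    num, _ = quad(
        lambda x: (1 - 2 * expit(x)) * pdf(x),
        max(a, -60.0),
        min(b, 60.0),
        epsabs=1e-13,
        limit=300,
    )
    return num / (expit(b) - expit(a))


class TestExpectedGradient:
    def test_symmetric_interval_gives_zero(self):
        y = OrdinalDataset(np.array([[2]]), [3])
        g = expected_gradient(y, np.zeros((1, 1)), [np.array([-1.0, 1.0])])
        assert abs(g[0, 0]) < 1e-15

    def test_binary_lower_category_matches_quadrature(self):
        y = OrdinalDataset(np.array([[1]]), [2])
        g = expected_gradient(y, np.zeros((1, 1)), [np.array([0.0])])
        assert g[0, 0] == pytest.approx(
            _quadrature_expected_gradient(0.0, [0.0], 1), abs=1e-8
        )

    def test_closed_form_equals_quadrature_on_random_grid(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 5))
            tau = np.sort(rng.normal(0, 2, k))
            while k > 1 and np.diff(tau).min() < 1e-3:
                tau = np.sort(rng.normal(0, 2, k))
            theta = float(rng.normal(0, 2))
            c = int(rng.integers(1, k + 2))
            y = OrdinalDataset(np.array([[c]]), [k + 1])
            g = expected_gradient(y, np.array([[theta]]), [tau])[0, 0]
            assert g == pytest.approx(
                _quadrature_expected_gradient(theta, tau, c), abs=1e-8
            )

    def test_bounded_by_one(self, rng):
        theta = rng.normal(0, 5, (20, 3))
        tau = [np.sort(rng.normal(0, 2, 2)) for _ in range(3)]
        y = OrdinalDataset(rng.integers(1, 4, (20, 3)), [3] * 3)
        g = expected_gradient(y, theta, tau)
        assert (np.abs(g) <= 1.0).all()


class TestWorkingResponses:
    def test_zero_gradient_fixed_point(self, rng):
        theta = rng.normal(0, 1, (5, 2))
        z = working_responses(theta, np.zeros_like(theta))
        np.testing.assert_array_equal(z, theta)

    def test_quadratic_majorizer_matches_bounded_newton_step(self):
        # minimising (B/2)(theta - ztilde)^2 gives theta_new = ztilde, which
        # must equal the Newton step theta - g/B with the bounded Hessian
        theta, g = 0.7, 0.23
        z = working_responses(np.array([[theta]]), np.array([[g]]))[0, 0]
        assert z == pytest.approx(theta - g / CURVATURE_BOUND, rel=1e-15)

    def test_continuity_in_theta(self):
        tau = [np.array([-1.0, 1.0])]
        grid = np.linspace(-8, 8, 2001)
        y = OrdinalDataset(np.full((grid.size, 1), 2), [3])
        g = expected_gradient(y, grid[:, None], tau)
        z = working_responses(grid[:, None], g)[:, 0]
        assert np.abs(np.diff(z)).max() < 0.1  # no jumps on a dense grid


class TestMajorizationValidity:
    def test_majorizer_touches_and_dominates(self, rng):
        """The quadratic majorizer of the expected complete-data objective
        touches at the current point and dominates on perturbations."""

        def expected_nll(theta_new, theta0, tau, c):
            # E[-log f(z - theta_new) | y = c, theta0] by quadrature
            full = np.concatenate(([-np.inf], tau, [np.inf]))
            a, b = full[c - 1] - theta0, full[c] - theta0
            pdf = lambda x: expit(x) * (1 - expit(x))
            mass = expit(b) - expit(a)

            def nlogf(t):
                # -log f(t) = t + 2 log(1 + exp(-t)), stable form
                return np.abs(t) + 2 * np.log1p(np.exp(-np.abs(t)))

            num, _ = quad(
                lambda x: nlogf(x + theta0 - theta_new) * pdf(x),
                max(a, -60.0),
                min(b, 60.0),
                epsabs=1e-12,
                limit=300,
            )
            return num / mass

        for _ in range(6):
            k = int(rng.integers(1, 4))
            tau = np.sort(rng.normal(0, 1.5, k))
            theta0 = float(rng.normal(0, 1.5))
            c = int(rng.integers(1, k + 2))
            y = OrdinalDataset(np.array([[c]]), [k + 1])
            g = expected_gradient(y, np.array([[theta0]]), [tau])[0, 0]
            e0 = expected_nll(theta0, theta0, tau, c)
            for delta in (-2.0, -0.5, -0.1, 0.1, 0.5, 2.0):
                maj = (
                    e0
                    + g * delta
                    + 0.5 * CURVATURE_BOUND * delta**2
                )
                actual = expected_nll(theta0 + delta, theta0, tau, c)
                assert maj >= actual - 1e-8
            # touches at zero perturbation
            assert expected_nll(theta0, theta0, tau, c) == pytest.approx(e0)
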