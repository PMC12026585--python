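from fractions import Fraction

import numpy as np
import pytest
from scipy.optimize import root

from genarith.powerlaw_cascade import (DomainError, InvalidCascadeError,
                                       build_end_product_cascade,
                                       evaluate_rates, jacobian,
                                       linearize_and_classify, model_from_json,
                                       model_to_json, simulate,
                                       solve_steady_state)


class TestBuild:
    def test_n3_has_one_intermediate(self):
        assert build_end_product_cascade(3).intermediate_count == 1

    def test_n9_has_seven_intermediates(self):
        assert build_end_product_cascade(9).intermediate_count == 7

    @pytest.mark.parametrize("n", range(3, 10))
    def test_intermediate_formula(self, n):
        assert build_end_product_cascade(n).intermediate_count == n - 2

    def test_n2_invalid(self):
        with pytest.raises(InvalidCascadeError):
            build_end_product_cascade(2)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(DomainError):
            build_end_product_cascade(3, alpha=[1, -1, 1])
        with pytest.raises(DomainError):
            build_end_product_cascade(3, beta=[0, 1, 1])

    def test_chain_structure(self):
        """Equation i >= 2 touches only species i-1 and i; equation 1 only 1 and n."""
        for n in range(3, 10):
            m = build_end_product_cascade(n)
            for eq in m.equations:
                touched = {
                    j for t in eq.production + eq.degradation
                    for j, e in enumerate(t.exponents) if not e.is_zero
                }
                i = eq.species_index
                if i == 1:
                    assert touched == {0, n - 1}
                else:
                    assert touched == {i - 2, i - 1}

    def test_negative_structural_g_rejected(self):
        with pytest.raises(DomainError):
            build_end_product_cascade(3, g=-1)


class TestEvaluateRates:
    def test_symmetric_fixed_point(self):
        m = build_end_product_cascade(5)
        for g in (0, 1, 3, Fraction(7, 2)):
            assert np.allclose(evaluate_rates(m, np.ones(5), g), 0.0)

    def test_hand_arithmetic(self):
        # dX1/dt = 2 * X3**(-1) - 1 * X1 = 2/2 - 1 = 0 at X=(1,1,2), structural g=1
        m = build_end_product_cascade(3, g=1, alpha=[2, 1, 1])
        rates = evaluate_rates(m, [1.0, 1.0, 2.0])
        assert rates[0] == pytest.approx(0.0, abs=1e-14)
        assert rates[1] == pytest.approx(0.0, abs=1e-14)   # 1*X1 - X2 = 0
        assert rates[2] == pytest.approx(-1.0, abs=1e-14)  # X2 - X3 = 1 - 2

    def test_matches_naive_oracle(self, rng):
        """Independent term-by-term monomial evaluation."""
        for _ in range(20):
            n = int(rng.integers(3, 8))
            alpha = rng.uniform(0.5, 2.0, n)
            beta = rng.uniform(0.5, 2.0, n)
            h = [Fraction(int(x)) for x in rng.integers(1, 4, n)]
            g = int(rng.integers(0, 4))
            m = build_end_product_cascade(n, g=g, alpha=alpha, beta=beta, h=h)
            X = rng.uniform(0.2, 3.0, n)
            expected = np.empty(n)
            expected[0] = alpha[0] * X[n - 1] ** (-g) - beta[0] * X[0] ** float(h[0])
            for i in range(1, n):
                expected[i] = alpha[i] * X[i - 1] - beta[i] * X[i] ** float(h[i])
            assert np.allclose(evaluate_rates(m, X, g), expected, rtol=1e-12)

    def test_nonpositive_state_rejected(self):
        m = build_end_product_cascade(3)
        with pytest.raises(DomainError):
            evaluate_rates(m, [1.0, 0.0, 1.0], 1)


class TestSteadyState:
    def test_symmetric_all_ones(self):
        for g in (0, 1, 2):
            ss = solve_steady_state(build_end_product_cascade(4), g)
            assert np.allclose(ss.concentrations, 1.0, atol=1e-12)
            assert ss.residual_norm <= 1e-10

    def test_matches_long_integration(self):
        m = build_end_product_cascade(3, g=1, alpha=[1.5, 1, 1])
        ss = solve_steady_state(m, 1)
        t = np.linspace(0, 1e4, 50)
        X = simulate(m, 1, 0.7 * np.ones(3), t)
        assert np.allclose(X[-1], ss.concentrations, rtol=1e-6)

    def test_linear_equals_newton(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 7))
            alpha = rng.uniform(0.5, 2.0, n)
            g = int(rng.integers(0, 2))
            m = build_end_product_cascade(n, g=g, alpha=alpha)
            lin = solve_steady_state(m, g, method="linear")
            newt = solve_steady_state(m, g, method="newton")
            assert np.allclose(lin.concentrations, newt.concentrations, rtol=1e-8)

    def test_matches_scipy_root_oracle(self):
        m = build_end_product_cascade(5, g=2, alpha=[1.3, 0.8, 1.0, 1.1, 0.9])
        ss = solve_steady_state(m, 2)
        sol = root(lambda y: evaluate_rates(m, np.exp(y), 2), np.zeros(5), tol=1e-13)
        assert sol.success
        assert np.allclose(ss.concentrations, np.exp(sol.x), rtol=1e-8)

    def test_fixed_point_consistency_random_stable(self, rng):
        """100 random stable models: residual of the solved state < 1e-8."""
        count = 0
        while count < 100:
            n = int(rng.integers(3, 8))
            alpha = rng.uniform(0.5, 2.0, n)
            beta = rng.uniform(0.5, 2.0, n)
            g = int(rng.integers(0, 2))  # g in {0,1} is stable for all these n
            m = build_end_product_cascade(n, g=g, alpha=alpha, beta=beta)
            ss = solve_steady_state(m, g)
            assert float(np.max(np.abs(evaluate_rates(m, ss.concentrations, g)))) < 1e-8
            count += 1


class TestSimulate:
    def test_constant_at_fixed_point(self):
        m = build_end_product_cascade(4, g=1)
        ss = solve_steady_state(m, 1)
        t = np.linspace(0, 10, 40)
        X = simulate(m, 1, ss.concentrations, t)
        assert np.allclose(X, ss.concentrations, rtol=1e-6)

    def test_positive_trajectory(self):
        m = build_end_product_cascade(5, g=2)
        X = simulate(m, 2, 0.1 * np.ones(5), np.linspace(0, 30, 200))
        assert np.all(X > 0)

    def test_n7_endpoint_matches_steady_state(self):
        m = build_end_product_cascade(7, g=1)
        ss = solve_steady_state(m, 1)
        X = simulate(m, 1, 0.5 * np.ones(7), np.linspace(0, 200, 400))
        assert np.allclose(X[-1], ss.concentrations, atol=1e-4)

    def test_end_product_overshoots_then_settles(self):
        """Started below the steady state, Xn rises above it before settling."""
        m = build_end_product_cascade(7, g=1)
        ss = solve_steady_state(m, 1)
        t = np.linspace(0, 150, 1500)
        X = simulate(m, 1, 0.4 * ss.concentrations, t)
        xn = X[:, -1]
        peak = int(np.argmax(xn))
        assert 0 < peak < len(t) - 1          # interior local max
        assert xn[peak] > ss.concentrations[-1] * (1 + 1e-3)
        assert abs(xn[-1] - ss.concentrations[-1]) < 1e-3

    def test_bad_grid_rejected(self):
        m = build_end_product_cascade(3)
        with pytest.raises(InvalidCascadeError):
            simulate(m, 1, np.ones(3), [0.0, 0.0, 1.0])


class TestStability:
    def test_n3_symmetric_feedback_stable_with_charpoly_oracle(self):
        """Eigenvalues of the 3x3 Jacobian are the roots of (l+1)^3 + g."""
        g = 1
        rep = linearize_and_classify(build_end_product_cascade(3), g)
        assert rep.classification == "stable"
        oracle = np.roots([1, 3, 3, 1 + g])
        assert np.allclose(sorted(rep.eigenvalues, key=lambda z: (z.real, z.imag)),
                           sorted(oracle, key=lambda z: (z.real, z.imag)), atol=1e-9)

    def test_no_feedback_pure_relaxation(self):
        rep = linearize_and_classify(build_end_product_cascade(3), 0)
        assert rep.classification == "stable"
        assert np.allclose(rep.eigenvalues.imag, 0.0, atol=1e-9)
        assert np.all(rep.eigenvalues.real < 0)

    def test_n7_sweep_transitions_to_oscillatory(self):
        m = build_end_product_cascade(7)
        classes = [linearize_and_classify(m, g).classification for g in range(0, 7)]
        assert classes[0] == "stable"
        assert "unstable_oscillatory" in classes
        first_unstable = classes.index("unstable_oscillatory")
        assert all(c == "stable" for c in classes[:first_unstable])
        # bisection refines the boundary; classic closed form is sec(pi/n)^n
        lo, hi = float(first_unstable - 1), float(first_unstable)
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            cls = linearize_and_classify(
                m, Fraction(mid).limit_denominator(10**6)).classification
            if cls == "stable":
                lo = mid
            else:
                hi = mid
        boundary = 0.5 * (lo + hi)
        assert boundary == pytest.approx((1 / np.cos(np.pi / 7)) ** 7, abs=1e-4)


class TestSerialization:
    def test_json_round_trip(self):
        m = build_end_product_cascade(5, g=3, alpha=[1, 2, 1, 1, 1])
        m2 = model_from_json(model_to_json(m))
        assert m2.n == m.n
        X = np.linspace(0.5, 1.5, 5)
        assert np.allclose(evaluate_rates(m, X), evaluate_rates(m2, X))

    def test_symbolic_round_trip(self):
        m = build_end_product_cascade(4)
        m2 = model_from_json(model_to_json(m))
        assert m2.is_symbolic
        assert np.allclose(evaluate_rates(m, np.ones(4), 2),
                           evaluate_rates(m2, np.ones(4), 2))
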