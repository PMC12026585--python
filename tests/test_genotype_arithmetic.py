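import json
from fractions import Fraction

import numpy as np
import pytest
import sympy

from genarith.config import RunConfig
from genarith.exponent_lattice import LatticeVector
from genarith.gexpr import G, as_gexpr
from genarith.genotype_arithmetic import (BistochasticityError, CompletionError,
                                          ConstraintSystem, GConstraint,
                                          aggregate_bistochastic,
                                          fixed_point_constraints,
                                          genotype_phenotype_ratios,
                                          max_projection_rows,
                                          permutation_from_basis,
                                          predict_binding_sites, solve_g_range,
                                          symbolic_feedback_vector)
from genarith.powerlaw_cascade import build_end_product_cascade


def b_vector(n):
    """(1, 0, ..., 0, g, 1) for a length-n cascade (dimension n+1)."""
    entries = [as_gexpr(0)] * n
    entries[0] = as_gexpr(1)
    entries[n - 1] = G
    return LatticeVector(entries=tuple(entries))


class TestFixedPointConstraints:
    def test_unit_vector_selecting_g(self):
        b = b_vector(7)
        h = tuple(int(j == 6) for j in range(8))
        sys_ = fixed_point_constraints([h], b)
        (c,) = sys_.constraints
        assert (c.coeff_g, c.constant) == (1, 0)  # g >= 0

    def test_last_two_coordinates(self):
        b = b_vector(7)
        h = (0, 0, 0, 0, 0, 0, 1, 1)
        (c,) = fixed_point_constraints([h], b).constraints
        assert (c.coeff_g, c.constant) == (1, 1)  # g + 1 >= 0

    def test_full_n7_basis_matches_sympy_oracle(self, n7_report):
        """Coefficient pattern re-derived with an independent symbolic engine."""
        g = sympy.Symbol("g")
        b_sym = [1, 0, 0, 0, 0, 0, g, 1]
        model = build_end_product_cascade(7)
        b = symbolic_feedback_vector(model)
        art = n7_report.artifacts[0]  # X1 cone, permuted-identity basis
        sys_ = fixed_point_constraints(art.permutation, b)
        assert len(sys_) == 8
        for c, h in zip(sys_.constraints, art.permutation):
            expr = sympy.expand(sum(bs * hh for bs, hh in zip(b_sym, h)))
            assert Fraction(str(expr.coeff(g, 1))) == c.coeff_g
            assert Fraction(str(expr.coeff(g, 0))) == c.constant

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            fixed_point_constraints([(1, 0)], b_vector(7))


class TestSolveGRange:
    def test_two_sided_interval(self):
        sys_ = ConstraintSystem(
            (GConstraint(1, -1), GConstraint(-1, 8)), ("a", "b"))
        r = solve_g_range(sys_)
        assert (r.lower, r.upper) == (1, 8)
        assert r.integer_candidates == tuple(range(1, 9))
        assert not r.truncated and not r.empty

    def test_half_line(self):
        r = solve_g_range(ConstraintSystem((GConstraint(1, 0),), ("a",)),
                          candidate_cap=5)
        assert (r.lower, r.upper) == (0, None)
        assert r.truncated
        assert r.integer_candidates == tuple(range(0, 6))

    def test_infeasible_flagged_not_raised(self):
        sys_ = ConstraintSystem(
            (GConstraint(1, -5), GConstraint(-1, 2)), ("a", "b"))
        r = solve_g_range(sys_)
        assert r.empty and r.integer_candidates == ()

    def test_constant_infeasible(self):
        r = solve_g_range(ConstraintSystem((GConstraint(0, -1),), ("a",)))
        assert r.empty

    def test_grid_scan_oracle_and_summed_containment(self, rng):
        """Random systems vs a fine rational grid; intersect within summed."""
        grid = [Fraction(k, 7) for k in range(-140, 141)]
        for _ in range(40):
            m = int(rng.integers(2, 11))
            cons = tuple(GConstraint(Fraction(int(rng.integers(-3, 4)), int(rng.integers(1, 4))),
                                     Fraction(int(rng.integers(-6, 7)), int(rng.integers(1, 3))))
                         for _ in range(m))
            sys_ = ConstraintSystem(cons, tuple(f"c{i}" for i in range(m)))
            inter = solve_g_range(sys_, "intersect", candidate_cap=20)
            summed = solve_g_range(sys_, "summed", candidate_cap=20)
            for x in grid:
                feasible = all(c.holds_at(x) for c in cons)
                assert feasible == inter.contains(x)
                if feasible:
                    assert summed.contains(x)  # summing weakens constraints

    def test_integer_candidates_exact_for_finite_interval(self):
        sys_ = ConstraintSystem(
            (GConstraint(2, 1), GConstraint(-3, 10)), ("a", "b"))
        r = solve_g_range(sys_)
        assert r.lower == Fraction(-1, 2) and r.upper == Fraction(10, 3)
        assert r.integer_candidates == (0, 1, 2, 3)


class TestAggregateBistochastic:
    def perm(self, order):
        n = len(order)
        m = np.zeros((n, n), dtype=int)
        for i, j in enumerate(order):
            m[i, j] = 1
        return m

    def test_eight_permutations_divided_by_8(self, rng):
        perms = [self.perm(rng.permutation(8)) for _ in range(8)]
        M = aggregate_bistochastic(perms, 8)
        rows, cols = M.line_sums()
        assert set(rows) == {1} and set(cols) == {1}

    def test_identity_trivially_bistochastic(self):
        M = aggregate_bistochastic([np.eye(3, dtype=int)], 1)
        assert M.values == tuple(tuple(Fraction(int(i == j)) for j in range(3))
                                 for i in range(3))

    def test_random_permutation_sums_birkhoff(self, rng):
        for _ in range(10):
            k = int(rng.integers(2, 7))
            count = int(rng.integers(1, 6))
            perms = [self.perm(rng.permutation(k)) for _ in range(count)]
            M = aggregate_bistochastic(perms, count)
            rows, cols = M.line_sums()
            assert set(rows) == {1} and set(cols) == {1}

    def test_non_permutation_input_raises(self):
        bad = np.ones((3, 3), dtype=int)
        with pytest.raises(BistochasticityError):
            aggregate_bistochastic([bad], 1)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            aggregate_bistochastic([np.eye(3, dtype=int), np.eye(4, dtype=int)], 2)


class TestRatios:
    def test_uniform_matrix(self):
        uniform = [[Fraction(1, 8)] * 8 for _ in range(8)]
        M = aggregate_bistochastic([uniform], 1)
        R = genotype_phenotype_ratios(M)
        assert all(x == Fraction(1, 8) for row in R for x in row)

    def test_entries_in_unit_interval_and_rows_sum_1(self, n7_report):
        R = genotype_phenotype_ratios(n7_report.bistochastic)
        for row in R:
            assert all(0 <= x <= 1 for x in row)
            assert sum(row) == 1


class TestMaxProjection:
    def test_identity_first_row(self):
        M = aggregate_bistochastic([np.eye(8, dtype=int)], 1)
        b = b_vector(7)
        # b(1) = (1,0,...,0,1,1): identity rows 0, 6, 7 tie at value 1
        assert max_projection_rows(M, b, 1) == [0, 6, 7]
        # with g = 2 the g-row dominates alone
        assert max_projection_rows(M, b, 2) == [6]

    def test_uniform_all_rows_tie(self):
        uniform = [[Fraction(1, 4)] * 4 for _ in range(4)]
        M = aggregate_bistochastic([uniform], 1)
        b = LatticeVector(entries=(as_gexpr(1), as_gexpr(0), G))
        assert max_projection_rows(M, b, 3) == [0, 1, 2, 3]

    def test_pipeline_matrix_matches_dot_product_oracle(self, n7_report):
        b = symbolic_feedback_vector(build_end_product_cascade(7))
        M = n7_report.bistochastic
        for g in (1, 2, 3):
            got = max_projection_rows(M, b, g)
            bv = [e.subs(g) for e in b.full]
            dots = [sum(x * y for x, y in zip(row, bv)) for row in M.values]
            expected = [i for i, v in enumerate(dots) if v == max(dots)]
            assert got == expected


class TestPermutationCompletion:
    def test_units_give_identity(self):
        rows = [tuple(int(i == j) for j in range(4)) for i in range(4)]
        P = permutation_from_basis(rows, 4)
        assert np.array_equal(P, np.eye(4, dtype=int))

    def test_difference_gives_transposition(self):
        rows = [(1, 0, 0), (0, 0, 1), (0, 1, -1)]
        P = permutation_from_basis(rows, 3)
        expected = np.array([[1, 0, 0], [0, 0, 1], [0, 1, 0]])
        assert np.array_equal(P, expected)

    def test_invalid_element_raises(self):
        with pytest.raises(CompletionError):
            permutation_from_basis([(2, -1, 0)], 3)


class TestPredict:
    def test_n7_divisor_is_8(self, n7_report):
        assert n7_report.divisor == 8  # 7 species cones + 1 constraint cone

    def test_divisor_rule_other_lengths(self):
        rep = predict_binding_sites(4, RunConfig(n=4, g_max=3))
        assert rep.divisor == 5

    def test_range_has_a_stable_candidate(self, n7_report):
        cands = set(n7_report.g_range.integer_candidates)
        assert any(n7_report.stability_at_candidates.get(g) == "stable"
                   for g in cands if g >= 0)

    def test_every_candidate_has_stability_entry(self, n7_report):
        for g in n7_report.g_range.integer_candidates:
            if g >= 0:
                assert g in n7_report.stability_at_candidates

    def test_deterministic_reports_byte_identical(self):
        a = predict_binding_sites(5, RunConfig(n=5, seed=3, g_max=4))
        b = predict_binding_sites(5, RunConfig(n=5, seed=3, g_max=4))
        ja = json.dumps(a.to_json_dict(), sort_keys=True)
        jb = json.dumps(b.to_json_dict(), sort_keys=True)
        assert ja == jb

    def test_constraint_soundness_exact(self, n7_report):
        """Every g in the intersect range satisfies all constraints exactly."""
        r = n7_report.g_range
        probes = [Fraction(g) for g in r.integer_candidates if g >= 0]
        probes += [Fraction(g) + Fraction(1, 3) for g in r.integer_candidates[:-1]
                   if g >= 0]
        for g in probes:
            if r.contains(g):
                assert n7_report.constraint_system.holds_at(g)

    def test_intersect_subset_of_summed(self, n7_report):
        r, s = n7_report.g_range, n7_report.g_range_summed
        # compare bounds directly (None = unbounded)
        if s.lower is not None:
            assert r.lower is not None and r.lower >= s.lower
        if s.upper is not None:
            assert r.upper is not None and r.upper <= s.upper

    def test_bistochastic_conservation(self):
        for n in (3, 5):
            rep = predict_binding_sites(n, RunConfig(n=n, g_max=3))
            rows, cols = rep.bistochastic.line_sums()
            assert set(rows) == {1} and set(cols) == {1}

    def test_out_of_range_length(self):
        from genarith.genotype_arithmetic import PipelineError
        with pytest.raises(PipelineError):
            predict_binding_sites(2)
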