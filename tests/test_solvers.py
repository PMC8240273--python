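"""Exact solvers: brute force, subset DP, ILP — individually and against
each other.  The central correctness property of the repository is the
three-way agreement on random instances."""

import pytest
from hypothesis import given, settings, strategies as st

from lrskit.dp_solver import AlphabetTooLargeError, solve_dp
from lrskit.ilp_solver import (
    HighsBackend,
    ILPError,
    build_ilp,
    solve_ilp,
    to_lp_string,
)
from lrskit.oracle import solve_bruteforce
from lrskit.runstring import (
    LRSError,
    compress,
    is_valid_selection,
    make_selection,
    selection_length,
)
from lrskit.simulate import random_instance

from conftest import WORKED_OPTIMUM

ALL_SOLVERS = [solve_bruteforce, solve_dp, solve_ilp]


@pytest.mark.parametrize("solver", ALL_SOLVERS)
class TestAllSolvers:
    def test_worked_example_optimum(self, solver, worked_rs):
        sel = solver(worked_rs)
        assert sel.total_length == WORKED_OPTIMUM
        assert is_valid_selection(worked_rs, sel)
        assert selection_length(worked_rs, sel) == WORKED_OPTIMUM

    def test_single_run(self, solver):
        assert solver(compress("aaaa")).total_length == 4

    def test_empty_instance(self, solver):
        sel = solver(compress([]))
        assert sel.total_length == 0 and sel.indices == ()

    def test_alternating_abcabc(self, solver):
        # merge the two a-runs by dropping b, c between, then take b and c
        assert solver(compress("abcabc")).total_length == 4

    def test_aba(self, solver):
        assert solver(compress("aba")).total_length == 2


class TestOracle:
    def test_run_cap_refusal(self):
        rs = compress("ab" * 12)
        with pytest.raises(LRSError, match="cap"):
            solve_bruteforce(rs, max_runs=20)

    def test_deterministic_tie_break_is_lexicographic(self):
        # "ab": both single runs selectable together; optimum is unique here,
        # but "aXbXa"-style co-optima must resolve to the smallest index set
        rs = compress("ab" + "a")  # runs (a)(b)(a): optima {1,2} and {1,3}... lengths 2
        sel = solve_bruteforce(rs)
        assert sel.total_length == 2
        assert sel.indices == (1, 2)  # lexicographically smallest optimum


class TestDP:
    def test_alphabet_cap_error_names_cap(self):
        rs = compress([f"t{i}" for i in range(30)] * 2)
        with pytest.raises(AlphabetTooLargeError, match="cap 25"):
            solve_dp(rs)

    def test_reversal_symmetry(self):
        for seed in range(30):
            rs = random_instance(15, 4, seed=seed)
            rev = compress(list(reversed([r.symbol for r in rs.runs for _ in range(r.length)])))
            assert solve_dp(rs).total_length == solve_dp(rev).total_length

    def test_relabeling_invariance(self):
        for seed in range(30):
            rs = random_instance(15, 4, seed=seed)
            relabeled = compress(
                [f"X{sym}" for r in rs.runs for sym in [r.symbol] * r.length]
            )
            assert solve_dp(rs).total_length == solve_dp(relabeled).total_length

    def test_fresh_symbol_append_adds_its_length(self):
        # disjoint-alphabet concatenation is additive; a fresh run is the
        # smallest case
        for seed in range(20):
            rs = random_instance(12, 3, seed=seed)
            base = solve_dp(rs).total_length
            extended = compress(
                [s for r in rs.runs for s in [r.symbol] * r.length] + ["fresh"] * 7
            )
            assert solve_dp(extended).total_length == base + 7


class TestILPModel:
    def test_worked_example_constraint_count(self, worked_rs):
        # same-symbol pairs: b1 (1,3)(1,5)(3,5), b3 (4,6)(4,8)(6,8)
        model = build_ilp(worked_rs)
        assert len(model.constraints) == 6
        assert model.constraint_bound == 16

    def test_aba_aggregated_constraint(self):
        model = build_ilp(compress("aba"))
        assert len(model.constraints) == 1
        con = model.constraints[0]
        # x_2 + 2 x_1 + 2 x_3 <= 4, i.e. x_2 <= 2 (2 - x_1 - x_3)
        assert dict(con.coeffs) == {2: 1, 1: 2, 3: 2}
        assert con.rhs == 4

    def test_distinct_symbols_no_constraints(self):
        rs = compress("abcd")
        model = build_ilp(rs)
        assert model.constraints == ()
        assert solve_ilp(rs).total_length == rs.m

    def test_constraint_count_bound_on_random_instances(self):
        for seed in range(40):
            rs = random_instance(20, 3, seed=seed)
            model = build_ilp(rs)
            assert len(model.constraints) <= model.constraint_bound

    def test_families_agree(self):
        for seed in range(25):
            rs = random_instance(18, 4, seed=seed)
            agg = solve_ilp(rs, constraint_family="aggregated").total_length
            pw = solve_ilp(rs, constraint_family="pairwise").total_length
            assert agg == pw

    def test_feasibility_matches_validity(self):
        # every run subset: ILP-feasible by substitution iff valid selection
        for seed in range(10):
            rs = random_instance(10, 3, seed=seed)
            model = build_ilp(rs)
            for mask in range(2 ** rs.n):
                x = [(mask >> i) & 1 for i in range(rs.n)]
                feasible = all(
                    sum(coef * x[i - 1] for i, coef in con.coeffs) <= con.rhs
                    for con in model.constraints
                )
                sel = make_selection(rs, [i + 1 for i in range(rs.n) if x[i]])
                assert feasible == is_valid_selection(rs, sel)

    def test_non_optimal_backend_raises(self, worked_rs):
        class FailingBackend:
            def solve(self, model):
                return "time limit reached", []

        with pytest.raises(ILPError, match="no proven optimum"):
            solve_ilp(worked_rs, backend=FailingBackend())

    def test_lp_export_mentions_all_variables(self, worked_rs):
        text = to_lp_string(build_ilp(worked_rs))
        assert "Maximize" in text and "Binary" in text
        for i in range(1, 9):
            assert f"x{i}" in text


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 10_000), st.integers(2, 6), st.integers(4, 16))
def test_three_way_agreement_on_random_instances(seed, s, m):
    """DP, ILP and brute force agree on uniformly random full-alphabet strings."""
    if m < s:
        m = s
    rs = random_instance(m, s, seed=seed)
    bf = solve_bruteforce(rs)
    dp = solve_dp(rs)
    ilp = solve_ilp(rs, backend=HighsBackend())
    assert bf.total_length == dp.total_length == ilp.total_length
    for sel in (bf, dp, ilp):
        assert is_valid_selection(rs, sel)
        assert selection_length(rs, sel) == sel.total_length
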