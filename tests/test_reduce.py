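"""Prefix/infix reduction rules: rule traces, disjointness invariants,
optimum preservation (the two decomposition lemmas)."""

import numpy as np
import pytest

from lrskit.dp_solver import solve_dp
from lrskit.oracle import solve_bruteforce
from lrskit.reduce import (
    decompose,
    find_independent_infixes,
    leaves,
    reassemble,
    split_prefix,
    tree_as_dict,
)
from lrskit.runstring import LRSError, compress, expand, is_valid_selection
from lrskit.simulate import random_instance
from lrskit.solver_api import SolveOptions, solve


def rs_of(s):
    return compress(list(s))


class TestPrefixRule:
    def test_shortest_independent_prefix(self):
        prefix, suffix = split_prefix(rs_of("abacc"))
        assert prefix.pairs() == (("a", 1), ("b", 1), ("a", 1))
        assert suffix.pairs() == (("c", 2),)

    def test_no_split_when_alphabet_never_closes(self):
        assert split_prefix(rs_of("abab")) is None

    def test_unique_symbols_split_immediately(self):
        prefix, suffix = split_prefix(rs_of("ab"))
        assert prefix.pairs() == (("a", 1),)
        assert suffix.pairs() == (("b", 1),)

    def test_empty_instance_rejected(self):
        with pytest.raises(LRSError):
            split_prefix(compress([]))

    def test_split_preserves_content(self):
        for seed in range(50):
            rs = random_instance(20, 5, seed=seed)
            result = split_prefix(rs)
            if result is None:
                continue
            prefix, suffix = result
            assert expand(prefix) + expand(suffix) == expand(rs)
            assert not (prefix.alphabet & suffix.alphabet)


class TestInfixRule:
    def test_closed_infix_found(self):
        # runs (a)(c)(d^2)(c)(a)(b)(a): anchor c closes the interval [2,4],
        # whose alphabet {c, d} never occurs outside it; the single-run
        # b-interval is discarded
        assert find_independent_infixes(rs_of("acddcaba")) == [(2, 4)]

    def test_merge_spanning_whole_string_yields_nothing(self):
        # runs (a)(c)(d^2)(c)(a)(b): the closed candidates [1,5], [2,4] and
        # the adjacent single-run [6,6] union into the full string, which is
        # no reduction — the prefix rule covers this split instead
        assert find_independent_infixes(rs_of("acddcab")) == []
        prefix, suffix = split_prefix(rs_of("acddcab"))
        assert prefix.n == 5 and suffix.n == 1

    def test_single_run_infix_discarded(self):
        assert find_independent_infixes(rs_of("aba")) == []

    def test_interleaved_symbols_yield_nothing(self):
        assert find_independent_infixes(rs_of("abab")) == []

    def test_adjacent_infixes_merge(self):
        # anchors b and c each give a single-run infix; merged they form a
        # usable 2-run reduction
        assert find_independent_infixes(rs_of("abca")) == [(2, 3)]

    def test_intervals_disjoint_alphabets(self):
        for seed in range(60):
            rs = random_instance(25, 6, seed=seed)
            intervals = find_independent_infixes(rs)
            seen_alphabets = []
            for p, q in intervals:
                assert q > p
                inner = {rs.run(k).symbol for k in range(p, q + 1)}
                outer = {
                    rs.run(k).symbol
                    for k in range(1, rs.n + 1)
                    if not p <= k <= q
                }
                assert not inner & outer
                for other in seen_alphabets:
                    assert not inner & other
                seen_alphabets.append(inner)
            # returned sorted and disjoint
            for (p1, q1), (p2, q2) in zip(intervals, intervals[1:]):
                assert q1 + 1 < p2


class TestDecompose:
    def solve_child(self, sub):
        return solve_bruteforce(sub)

    def test_two_singleton_leaves(self):
        tree = decompose(rs_of("ab"), self.solve_child)
        assert len(leaves(tree)) == 2

    def test_worked_example_is_irreducible(self, worked_rs):
        tree = decompose(worked_rs, self.solve_child)
        lvs = leaves(tree)
        assert len(lvs) == 1
        assert lvs[0].instance.pairs() == worked_rs.pairs()

    def test_nested_rule_trace(self):
        # (a^2)(b)(c)(d^2)(c)(b)(e): prefix (a^2) splits; then
        # (b)(c)(d^2)(c)(b) closes before (e); inside it the infix
        # (c)(d^2)(c) is solved and replaced by a placeholder
        rs = compress("aabcddcbe")
        seen_infix = []

        def solving(sub):
            seen_infix.append(sub.pairs())
            return solve_bruteforce(sub)

        tree = decompose(rs, solving)
        assert (("c", 1), ("d", 2), ("c", 1)) in seen_infix
        sols = [solve_bruteforce(leaf.instance) for leaf in leaves(tree)]
        sel = reassemble(tree, sols, rs)
        assert sel.total_length == solve_bruteforce(rs).total_length

    def test_reassembled_selection_is_valid_and_optimal(self):
        for seed in range(60):
            rs = random_instance(22, 6, seed=seed)
            tree = decompose(rs, self.solve_child)
            sols = [solve_bruteforce(leaf.instance) for leaf in leaves(tree)]
            sel = reassemble(tree, sols, rs)
            assert is_valid_selection(rs, sel)
            assert sel.total_length == solve_bruteforce(rs).total_length

    def test_mismatched_solutions_raise(self, worked_rs):
        tree = decompose(worked_rs, self.solve_child)
        with pytest.raises(LRSError, match="leaf solutions"):
            reassemble(tree, [], worked_rs)

    def test_tree_as_dict_shape(self):
        tree = decompose(rs_of("aabccbd"), self.solve_child)
        d = tree_as_dict(tree)
        assert d["kind"] in ("leaf", "prefix-split")


class TestLemmas:
    def test_disjoint_concatenation_is_additive(self):
        # LRS(A . B) = LRS(A) + LRS(B) for disjoint alphabets
        rng = np.random.default_rng(0)
        for k in range(30):
            a = random_instance(int(rng.integers(3, 12)), 3, seed=200 + k)
            b_tokens = [
                f"z{r.symbol}" for r in random_instance(int(rng.integers(3, 12)), 3, seed=400 + k).runs
                for _ in range(r.length)
            ]
            combined = compress(list(expand(a)) + b_tokens)
            assert (
                solve_bruteforce(combined).total_length
                == solve_bruteforce(a).total_length
                + solve_bruteforce(compress(b_tokens)).total_length
            )

    def test_infix_placeholder_substitution(self):
        # LRS(s1..sl T sl+1..sm) = LRS(s1..sl $^LRS(T) sl+1..sm)
        rng = np.random.default_rng(1)
        for k in range(30):
            s = list("".join(rng.choice(list("abc"), size=int(rng.integers(2, 12)))))
            t = ["z" + c for c in rng.choice(list("xy"), size=int(rng.integers(2, 8)))]
            cut = int(rng.integers(0, len(s) + 1))
            lrs_t = solve_bruteforce(compress(t)).total_length
            spliced = compress(s[:cut] + t + s[cut:])
            placeheld = compress(s[:cut] + ["$"] * lrs_t + s[cut:])
            assert (
                solve_bruteforce(spliced).total_length
                == solve_bruteforce(placeheld).total_length
            )

    def test_reduction_soundness_against_plain_solve(self):
        for seed in range(40):
            rs = random_instance(25, 6, seed=seed)
            with_rules = solve(rs).optimum
            without = solve(
                rs, SolveOptions(use_prefix_rule=False, use_infix_rule=False)
            ).optimum
            assert with_rules == without == solve_dp(rs).total_length
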