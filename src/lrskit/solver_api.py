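"""End-to-end solving: shortcuts, reductions, hybrid dispatch, reassembly.

This is the package's public entry point.  ``solve`` applies, in order:

1. a *singleton shortcut* — if the instance has at most one run, or every
   symbol occurs in exactly one run, all runs form the optimum and no
   solver is invoked (setting up a solver would dominate the cost on the
   near-trivial sub-instances that real scaffolding data mostly reduces to);
2. the prefix/infix reduction rules (:mod:`lrskit.reduce`), both optional;
3. per irreducible leaf, an exact algorithm chosen by the hybrid rule —
   the ILP when the leaf's size is below ``coefficient * (|alphabet| -
   offset)`` with empirical defaults coefficient 10, offset 13, the DP
   otherwise.  The DP scales exponentially in alphabet size but mildly in
   length, the ILP the other way round, so the rule hands each leaf to the
   algorithm suited to its shape.  Leaves above the DP alphabet cap always
   go to the ILP;
4. reassembly of leaf optima into a selection on the original instance.

Dispatch is evaluated per reduced leaf, not on the original instance,
because leaves are what the solvers actually see.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from . import dp_solver, ilp_solver, oracle
from .reduce import decompose, leaves, reassemble
from .runstring import (
    LRSError,
    RunString,
    Selection,
    compress,
    is_valid_selection,
    make_selection,
)

ALGORITHMS = ("auto", "dp", "ilp", "bruteforce")
LENGTH_MEASURES = ("expanded", "runs")


@dataclass(frozen=True)
class SolveOptions:
    """Knobs for :func:`solve`.

    ``hybrid_coefficient`` / ``hybrid_offset`` are the constants of the
    dispatch rule (defaults 10 and 13); ``length_measure`` selects whether
    the rule's size is the expanded string length (default) or the run
    count.
    """

    algorithm: str = "auto"
    use_prefix_rule: bool = True
    use_infix_rule: bool = True
    hybrid_coefficient: int = 10
    hybrid_offset: int = 13
    length_measure: str = "expanded"
    dp_alphabet_cap: int = dp_solver.DEFAULT_ALPHABET_CAP
    bruteforce_run_cap: int = oracle.DEFAULT_MAX_RUNS
    ilp_constraint_family: str = "aggregated"
    backend: Optional[ilp_solver.MIPBackend] = None
    seed: Optional[int] = None
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise LRSError(f"unknown algorithm {self.algorithm!r}; expected {ALGORITHMS}")
        if self.length_measure not in LENGTH_MEASURES:
            raise LRSError(
                f"unknown length measure {self.length_measure!r}; expected {LENGTH_MEASURES}"
            )


@dataclass(frozen=True)
class LeafReport:
    """What was solved at one irreducible leaf and how."""

    n_runs: int
    length: int
    alphabet_size: int
    algorithm: str  # "shortcut" | "dp" | "ilp" | "bruteforce"


@dataclass(frozen=True)
class SolveResult:
    """Optimal selection plus a per-leaf solving report."""

    selection: Selection
    optimum: int
    dropped: tuple[int, ...]  # conflicting run indices (1-based)
    leaf_reports: tuple[LeafReport, ...] = field(default=())

    @property
    def leaf_count(self) -> int:
        return len(self.leaf_reports)

    @property
    def algorithms_used(self) -> tuple[str, ...]:
        return tuple(sorted({r.algorithm for r in self.leaf_reports}))


def choose_algorithm(rs: RunString, opts: SolveOptions | None = None) -> str:
    """Hybrid dispatch: ``"ilp"`` iff size < coefficient * (|alphabet| - offset),
    else ``"dp"``; an alphabet above the DP cap always dispatches to the ILP."""
    opts = opts or SolveOptions()
    sigma = len(rs.alphabet)
    if sigma > opts.dp_alphabet_cap:
        return "ilp"
    size = rs.m if opts.length_measure == "expanded" else rs.n
    if size < opts.hybrid_coefficient * (sigma - opts.hybrid_offset):
        return "ilp"
    return "dp"


def _trivial(rs: RunString) -> bool:
    """All runs are selectable as-is: at most one run, or one run per symbol."""
    return rs.n <= 1 or len(rs.alphabet) == rs.n


def _solve_leaf(rs: RunString, opts: SolveOptions, reports: list[LeafReport]) -> Selection:
    sigma = len(rs.alphabet)
    if _trivial(rs):
        reports.append(LeafReport(rs.n, rs.m, sigma, "shortcut"))
        return make_selection(rs, range(1, rs.n + 1))
    algo = opts.algorithm
    if algo == "auto":
        algo = choose_algorithm(rs, opts)
    reports.append(LeafReport(rs.n, rs.m, sigma, algo))
    if algo == "dp":
        return dp_solver.solve_dp(rs, alphabet_cap=opts.dp_alphabet_cap)
    if algo == "ilp":
        return ilp_solver.solve_ilp(
            rs, backend=opts.backend, constraint_family=opts.ilp_constraint_family
        )
    return oracle.solve_bruteforce(rs, max_runs=opts.bruteforce_run_cap)


def _solve_rec(rs: RunString, opts: SolveOptions, reports: list[LeafReport]) -> Selection:
    if _trivial(rs) or not (opts.use_prefix_rule or opts.use_infix_rule):
        return _solve_leaf(rs, opts, reports)
    tree = decompose(
        rs,
        solve_child=lambda sub: _solve_rec(sub, opts, reports),
        use_prefix=opts.use_prefix_rule,
        use_infix=opts.use_infix_rule,
    )
    sols = [_solve_leaf(leaf.instance, opts, reports) for leaf in leaves(tree)]
    return reassemble(tree, sols, rs)


def solve(rs: RunString, opts: SolveOptions | None = None) -> SolveResult:
    """Solve an LRS instance to proven optimality.

    Returns the optimal :class:`Selection`, the conflicting (dropped) run
    indices, and a report of per-leaf sizes and algorithms used.  The
    selection and dropped set partition the run indices 1..n.
    """
    opts = opts or SolveOptions()
    reports: list[LeafReport] = []
    sel = _solve_rec(rs, opts, reports)
    assert is_valid_selection(rs, sel)
    dropped = tuple(i for i in range(1, rs.n + 1) if i not in set(sel.indices))
    return SolveResult(sel, sel.total_length, dropped, tuple(reports))


def solve_tokens(tokens: Sequence, opts: SolveOptions | None = None) -> SolveResult:
    """Convenience wrapper: run-length compress a token sequence and solve."""
    return solve(compress(tokens), opts)


def lrs_length(tokens_or_rs, opts: SolveOptions | None = None) -> int:
    """The LRS value itself — length of a longest run subsequence."""
    rs = tokens_or_rs if isinstance(tokens_or_rs, RunString) else compress(tokens_or_rs)
    return solve(rs, opts).optimum


def with_algorithm(opts: SolveOptions, algorithm: str) -> SolveOptions:
    """Copy of ``opts`` with a forced algorithm (helper for benchmarks/tests)."""
    return replace(opts, algorithm=algorithm)
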