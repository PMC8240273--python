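"""Brute-force exact reference solver.

Enumerates run subsets in lexicographic order of their index sets with an
include-first depth-first search.  Invalid branches are pruned as soon as a
symbol would reopen, and a remaining-length bound cuts subtrees that cannot
strictly improve the incumbent; because enumeration is lexicographic and
updates are strict, the returned optimum is the lexicographically smallest
index set among all optima.  Intended for testing and tiny instances only.
"""

from __future__ import annotations

from .runstring import (
    LRSError,
    RunString,
    Selection,
    is_valid_selection,
    make_selection,
)

DEFAULT_MAX_RUNS = 22


def solve_bruteforce(rs: RunString, max_runs: int = DEFAULT_MAX_RUNS) -> Selection:
    """Exact optimum by exhaustive enumeration over the 2^n run subsets.

    Refuses instances with more than ``max_runs`` runs to prevent accidental
    exponential blow-ups in tests.
    """
    n = rs.n
    if n > max_runs:
        raise LRSError(
            f"brute force refused: instance has {n} runs, cap is {max_runs}"
        )
    if n == 0:
        return make_selection(rs, ())

    lengths = [r.length for r in rs.runs]
    symbols = [r.symbol for r in rs.runs]
    # suffix[i] = total length of runs i+1..n (0-based i)
    suffix = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] + lengths[i]

    best_len = 0
    best_idx: tuple[int, ...] = ()
    chosen: list[int] = []

    def dfs(i: int, cur_len: int, prev_sym, closed: frozenset) -> None:
        nonlocal best_len, best_idx
        if cur_len + suffix[i] <= best_len:
            return  # cannot strictly beat the incumbent
        if i == n:
            if cur_len > best_len:
                best_len = cur_len
                best_idx = tuple(chosen)
            return
        sym = symbols[i]
        # include run i+1 first: lexicographic order over index sets
        if sym == prev_sym:
            chosen.append(i + 1)
            dfs(i + 1, cur_len + lengths[i], sym, closed)
            chosen.pop()
        elif sym not in closed:
            chosen.append(i + 1)
            nxt_closed = closed | {prev_sym} if prev_sym is not None else closed
            dfs(i + 1, cur_len + lengths[i], sym, nxt_closed)
            chosen.pop()
        # exclude run i+1
        dfs(i + 1, cur_len, prev_sym, closed)

    dfs(0, 0, None, frozenset())
    sel = make_selection(rs, best_idx)
    assert is_valid_selection(rs, sel)
    return sel
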