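"""NP-hardness construction: linear ordering problem (LOP) -> LRS.

The LRS decision problem is NP-complete by reduction from LOP: given a
complete weighted digraph G on n vertices (no self-loops, weights positive
after normalization), a run string S is built such that G has a vertex
ordering of forward weight k iff S has a run subsequence of length

    f_G(k) = (n-1) * M  +  n(n-1)(n-2)/3 * M'  +  n(n-1) * w_sum  +  2k

with M' = 4 n^2 w_sum and M = M' n^3.  The alphabet has three tiers:

* separator symbols $_i, one run of length M between consecutive vertex
  blocks (n symbols defined, n-1 runs occur) — M dwarfs everything else, so
  every optimum keeps all separators, which pins edge-sign choices to a
  single vertex block;
* edge signs E_{i,j} = E_{j,i}, one per unordered vertex pair; the edge
  block for ordered pair (i,j) is E^{w_ij + w_sum} (triangles) E^{w_ij + w_sum},
  so taking *both* edge runs of one block (merging across dropped triangle
  runs) encodes orienting the pair as (i, j);
* triangle signs D_(i,j,k), identified up to rotation, one run of length M'
  in each of the three edge blocks of its triangle — M' exceeds all edge
  runs combined, so every optimum selects one run per triangle sign, which
  forbids orienting all three edges of any triangle cyclically; excluding
  3-cycles excludes all cycles in a tournament.

This module generates the construction exactly, evaluates f_G, solves tiny
LOP instances exhaustively, and verifies the equivalence end-to-end (the
self-verifying harness).  Instances are kept in run-length form only: the
expanded string is astronomically long by design, so expansion is refused
above a size guard.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .runstring import LRSError, RunString, Selection

EXPAND_GUARD = 10**6  # refuse expanding hardness instances longer than this


@dataclass(frozen=True)
class CompleteDigraph:
    """LOP instance: n vertices (1-based), integer weight per ordered pair."""

    n: int
    w: dict = field(default_factory=dict)  # (i, j) -> weight, i != j

    def __post_init__(self) -> None:
        if self.n < 2:
            raise LRSError("a LOP instance needs at least 2 vertices")
        for i in range(1, self.n + 1):
            for j in range(1, self.n + 1):
                if i != j and (i, j) not in self.w:
                    raise LRSError(f"missing weight for ordered pair ({i}, {j})")

    @property
    def w_sum(self) -> int:
        return sum(self.w.values())

    @classmethod
    def from_matrix(cls, matrix) -> "CompleteDigraph":
        """Build from a square matrix (diagonal ignored)."""
        mat = [list(row) for row in matrix]
        n = len(mat)
        w = {
            (i + 1, j + 1): int(mat[i][j])
            for i in range(n)
            for j in range(n)
            if i != j
        }
        return cls(n, w)

    @classmethod
    def random(cls, n: int, lo: int = 1, hi: int = 5, seed: Optional[int] = None) -> "CompleteDigraph":
        """Uniform integer weights in [lo, hi]."""
        rng = np.random.default_rng(seed)
        w = {
            (i, j): int(rng.integers(lo, hi + 1))
            for i in range(1, n + 1)
            for j in range(1, n + 1)
            if i != j
        }
        return cls(n, w)


@dataclass(frozen=True)
class HardnessInstance:
    """The constructed run string plus the bookkeeping the harness checks."""

    instance: RunString
    graph: CompleteDigraph
    m_big: int  # M  (separator run length)
    m_prime: int  # M' (triangle run length)
    w_sum: int
    separator_symbols: tuple[str, ...]  # all n defined; n-1 occur
    edge_symbols: tuple[str, ...]
    triangle_symbols: tuple[str, ...]
    provenance: tuple  # per run: ("sep", i) | ("edge", i, j, side) | ("tri", canon)

    @property
    def defined_alphabet_size(self) -> int:
        return (
            len(self.separator_symbols)
            + len(self.edge_symbols)
            + len(self.triangle_symbols)
        )


def normalize_weights(g: CompleteDigraph) -> tuple[CompleteDigraph, int]:
    """Shift all weights by a uniform offset so that each is >= 1.

    The number of forward edges in any ordering is fixed (n(n-1)/2), so the
    shift adds a constant to every LOP objective; the returned offset lets
    callers translate objective values back.
    """
    lo = min(g.w.values())
    offset = 1 - lo if lo <= 0 else 0
    if offset == 0:
        return g, 0
    return CompleteDigraph(g.n, {k: v + offset for k, v in g.w.items()}), offset


def separator_symbol(i: int) -> str:
    return f"$_{i}"


def edge_symbol(i: int, j: int) -> str:
    a, b = sorted((i, j))
    return f"E_{a}_{b}"


def triangle_symbol(i: int, j: int, k: int) -> str:
    """Canonical name: lexicographically smallest rotation of (i, j, k)."""
    rotations = [(i, j, k), (j, k, i), (k, i, j)]
    a, b, c = min(rotations)
    return f"T_{a}_{b}_{c}"


def f_g(k: int, g: CompleteDigraph) -> int:
    """The length map of the reduction, in exact integer arithmetic."""
    n = g.n
    w_sum = g.w_sum
    m_prime = 4 * n * n * w_sum
    m_big = m_prime * n**3
    return (
        (n - 1) * m_big
        + (n * (n - 1) * (n - 2) // 3) * m_prime
        + n * (n - 1) * w_sum
        + 2 * k
    )


def lop_to_lrs(g: CompleteDigraph) -> HardnessInstance:
    """Build the LRS instance encoding a (normalized) LOP instance.

    Vertex blocks appear in order v_1..v_n, separated by $_i^M.  Vertex
    block i holds an edge block per ordered pair (i, j), j ascending; the
    edge block is E_{i,j}^{w_ij + w_sum}, the n-2 triangle runs (k
    ascending), then E_{i,j}^{w_ij + w_sum} again.
    """
    n = g.n
    if n < 3:
        raise LRSError("hardness construction needs n >= 3 (no triangles otherwise)")
    if min(g.w.values()) < 1:
        raise LRSError("weights must be normalized to >= 1 first")
    w_sum = g.w_sum
    m_prime = 4 * n * n * w_sum
    m_big = m_prime * n**3

    pairs: list[tuple[str, int]] = []
    prov: list[tuple] = []
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if j == i:
                continue
            e = edge_symbol(i, j)
            w_run = g.w[(i, j)] + w_sum
            pairs.append((e, w_run))
            prov.append(("edge", i, j, "left"))
            for k in range(1, n + 1):
                if k in (i, j):
                    continue
                pairs.append((triangle_symbol(i, j, k), m_prime))
                prov.append(("tri", triangle_symbol(i, j, k)))
            pairs.append((e, w_run))
            prov.append(("edge", i, j, "right"))
        if i < n:
            pairs.append((separator_symbol(i), m_big))
            prov.append(("sep", i))

    edge_syms = tuple(
        edge_symbol(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)
    )
    tri_syms = tuple(
        sorted(
            {
                triangle_symbol(i, j, k)
                for i, j, k in itertools.permutations(range(1, n + 1), 3)
            }
        )
    )
    return HardnessInstance(
        instance=RunString.from_pairs(pairs),
        graph=g,
        m_big=m_big,
        m_prime=m_prime,
        w_sum=w_sum,
        separator_symbols=tuple(separator_symbol(i) for i in range(1, n + 1)),
        edge_symbols=edge_syms,
        triangle_symbols=tri_syms,
        provenance=tuple(prov),
    )


def expand_instance(hi: HardnessInstance):
    """Expanded token sequence of a hardness instance, guarded by size.

    Run lengths are in the millions by construction, so expansion is refused
    above ``EXPAND_GUARD`` characters; solvers operate on the run-length
    form only.
    """
    from .runstring import expand

    if hi.instance.m > EXPAND_GUARD:
        raise LRSError(
            f"refusing to expand hardness instance of length {hi.instance.m} "
            f"(> {EXPAND_GUARD}); use the run-length form"
        )
    return expand(hi.instance)


def solve_lop_bruteforce(g: CompleteDigraph, max_n: int = 8) -> tuple[tuple[int, ...], int]:
    """Exhaustive LOP: the ordering maximizing total forward-edge weight.

    Ties go to the lexicographically smallest permutation.  Refuses n above
    ``max_n`` (n! enumeration).
    """
    if g.n > max_n:
        raise LRSError(f"exhaustive LOP refused for n={g.n} > {max_n}")
    best_perm: tuple[int, ...] | None = None
    best_val = -1
    for perm in itertools.permutations(range(1, g.n + 1)):
        val = sum(
            g.w[(perm[a], perm[b])]
            for a in range(g.n)
            for b in range(a + 1, g.n)
        )
        if val > best_val:
            best_val = val
            best_perm = perm
    assert best_perm is not None
    return best_perm, best_val


def check_optimal_structure(hi: HardnessInstance, sel: Selection) -> dict:
    """Structural facts about an optimal selection, via the provenance map.

    Returns counts used by the harness invariants: every separator run
    selected, exactly one run per triangle sign, and per unordered pair one
    edge block contributing both edge runs.
    """
    selected = [hi.provenance[i - 1] for i in sel.indices]
    sep_runs = sum(1 for p in selected if p[0] == "sep")
    tri_counts: dict[str, int] = {}
    edge_sides: dict[tuple, set] = {}
    for p in selected:
        if p[0] == "tri":
            tri_counts[p[1]] = tri_counts.get(p[1], 0) + 1
        elif p[0] == "edge":
            edge_sides.setdefault((p[1], p[2]), set()).add(p[3])
    full_blocks = {pair for pair, sides in edge_sides.items() if sides == {"left", "right"}}
    return {
        "separators_selected": sep_runs,
        "separators_expected": hi.graph.n - 1,
        "triangle_counts": tri_counts,
        "full_edge_blocks": full_blocks,
    }


def orientation_from_selection(hi: HardnessInstance, sel: Selection) -> dict:
    """The tournament read off an optimal selection: unordered pair -> chosen
    ordered pair (the edge block whose two edge runs are both selected)."""
    struct = check_optimal_structure(hi, sel)
    return {tuple(sorted(p)): p for p in struct["full_edge_blocks"]}


def verify_theorem(g: CompleteDigraph, solve_fn) -> dict:
    """Self-verifying harness for one graph.

    Normalizes weights, solves LOP exhaustively (optimum k*), builds the LRS
    instance, solves it with ``solve_fn(RunString) -> Selection`` and checks
    LRS optimum == f_G(k*).  Returns the full record.
    """
    g_norm, offset = normalize_weights(g)
    perm, k_star = solve_lop_bruteforce(g_norm)
    hi = lop_to_lrs(g_norm)
    sel = solve_fn(hi.instance)
    expected = f_g(k_star, g_norm)
    return {
        "n": g.n,
        "offset": offset,
        "lop_optimum": k_star,
        "lop_ordering": perm,
        "lrs_optimum": sel.total_length,
        "expected": expected,
        "match": sel.total_length == expected,
        "instance": hi,
        "selection": sel,
    }
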