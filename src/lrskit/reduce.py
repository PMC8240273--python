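"""Provably-safe instance decomposition.

Two optimum-preserving rules shrink an instance before any solver runs:

*Prefix rule* — if a prefix of runs uses an alphabet disjoint from the rest
of the string, the two parts can be solved independently and their optima
concatenated (disjoint alphabets cannot interact).  The rule is iterated,
cutting the string into maximal independent pieces.

*Infix rule* — if an infix uses an exclusive alphabet, its contribution to
any optimum is either nothing or its own full optimum.  The infix is solved
recursively and replaced in the outer instance by a single placeholder run
of a fresh symbol whose length equals the infix optimum; the outer optimum
is unchanged.

Orchestration: exhaust the prefix rule, then search each piece for
independent infixes; every infix found is solved recursively (starting with
the prefix rule again) and substituted; the substituted outer instance is
decomposed again.  Leaves of the resulting tree are irreducible.

The tree is represented by :class:`Concat` / :class:`Leaf` nodes.  Each run
of a leaf carries a provenance entry: either the original run index, or a
solved placeholder recording the replaced child's provenance and its local
optimal selection, which is all :func:`reassemble` needs to splice child
optima back into a selection over the original instance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Union

from .runstring import LRSError, RunString, Selection, make_selection


class PlaceholderToken:
    """Fresh symbol for a replaced infix; compares by identity only, so it can
    never collide with any input token."""

    __slots__ = ("tag",)
    _counter = 0

    def __init__(self) -> None:
        PlaceholderToken._counter += 1
        self.tag = PlaceholderToken._counter

    def __repr__(self) -> str:
        return f"$#{self.tag}"


@dataclass(frozen=True)
class Original:
    """Provenance: this leaf run is original run ``index`` (1-based)."""

    index: int


@dataclass(frozen=True)
class SolvedInfix:
    """Provenance: this leaf run is a placeholder for a solved infix.

    ``prov`` is the replaced child's per-run provenance and ``selection`` the
    child's optimal selection in child-local indices; ``symbol`` the
    placeholder token.
    """

    prov: tuple
    selection: Selection
    symbol: PlaceholderToken


Prov = Union[Original, SolvedInfix]


@dataclass(frozen=True)
class Leaf:
    """Irreducible sub-instance plus per-run provenance."""

    instance: RunString
    prov: tuple


@dataclass(frozen=True)
class Concat:
    """Prefix-rule split into alphabet-disjoint pieces, in string order."""

    children: tuple


ReductionTree = Union[Leaf, Concat]


def split_prefix(rs: RunString) -> tuple[RunString, RunString] | None:
    """Shortest independent prefix split, or ``None`` if none exists.

    Start with run 1 and let p be the last occurrence of its symbol; for
    l = 2, 3, ... raise p to the last occurrence of sigma(r_l); stop once
    l > p.  If p < n the prefix runs 1..p and suffix runs p+1..n have
    disjoint alphabets.
    """
    if rs.n == 0:
        raise LRSError("split_prefix needs a non-empty instance")
    last: dict = {}
    for idx, r in enumerate(rs.runs, start=1):
        last[r.symbol] = idx
    p = last[rs.runs[0].symbol]
    l = 2
    while l <= p:
        p = max(p, last[rs.runs[l - 1].symbol])
        l += 1
    if p >= rs.n:
        return None
    return rs.slice_runs(1, p), rs.slice_runs(p + 1, rs.n)


def iterate_prefix_splits(rs: RunString) -> list[tuple[int, int]]:
    """Run-index intervals of the maximal prefix-rule pieces, in order."""
    pieces: list[tuple[int, int]] = []
    offset = 0
    cur = rs
    while cur.n:
        split = split_prefix(cur)
        if split is None:
            pieces.append((offset + 1, offset + cur.n))
            break
        prefix, suffix = split
        pieces.append((offset + 1, offset + prefix.n))
        offset += prefix.n
        cur = suffix
    return pieces


def find_independent_infixes(rs: RunString) -> list[tuple[int, int]]:
    """Disjoint run-index intervals [p, q] with exclusive alphabets.

    For each anchor symbol, start from its first/last occurrence and expand
    the interval whenever an enclosed symbol occurs outside, until the
    interval is alphabet-closed or covers the whole string.  Closed proper
    intervals are collected; overlapping, nested or adjacent intervals are
    merged; intervals of a single run are discarded (no actual reduction).
    Cost O(n * |alphabet|) up to the fixed-point expansion.
    """
    n = rs.n
    if n == 0:
        return []
    first: dict = {}
    last: dict = {}
    for idx, r in enumerate(rs.runs, start=1):
        first.setdefault(r.symbol, idx)
        last[r.symbol] = idx

    candidates: list[tuple[int, int]] = []
    seen: set = set()
    for r in rs.runs:
        sigma = r.symbol
        if sigma in seen:
            continue
        seen.add(sigma)
        p, q = first[sigma], last[sigma]
        changed = True
        while changed and (q - p + 1) < n:
            changed = False
            for k in range(p, q + 1):
                tau = rs.runs[k - 1].symbol
                if first[tau] < p:
                    p = first[tau]
                    changed = True
                if last[tau] > q:
                    q = last[tau]
                    changed = True
        if (q - p + 1) < n:
            candidates.append((p, q))

    if not candidates:
        return []
    candidates.sort()
    merged = [candidates[0]]
    for p, q in candidates[1:]:
        mp, mq = merged[-1]
        if p <= mq + 1:  # overlapping, nested or adjacent
            merged[-1] = (mp, max(mq, q))
        else:
            merged.append((p, q))
    return [(p, q) for p, q in merged if q > p and (q - p + 1) < n]


def decompose(
    rs: RunString,
    solve_child: Callable[[RunString], Selection],
    use_prefix: bool = True,
    use_infix: bool = True,
) -> ReductionTree:
    """Decompose an instance into irreducible leaves.

    ``solve_child`` is invoked on every independent infix to obtain its
    optimum (the placeholder run length); decomposition is therefore
    interleaved with solving, as the infix rule requires.
    """
    prov = tuple(Original(i) for i in range(1, rs.n + 1))
    return _decompose(rs, prov, solve_child, use_prefix, use_infix)


def _decompose(rs, prov, solve_child, use_prefix, use_infix) -> ReductionTree:
    if use_prefix and rs.n:
        pieces = iterate_prefix_splits(rs)
        if len(pieces) > 1:
            children = []
            for p, q in pieces:
                sub = rs.slice_runs(p, q)
                children.append(
                    _decompose(sub, prov[p - 1 : q], solve_child, use_prefix, use_infix)
                )
            return Concat(tuple(children))
    if use_infix and rs.n:
        intervals = find_independent_infixes(rs)
        if intervals:
            new_pairs: list = []
            new_prov: list = []
            cursor = 1
            for p, q in intervals:
                for k in range(cursor, p):
                    new_pairs.append(rs.pairs()[k - 1])
                    new_prov.append(prov[k - 1])
                child = rs.slice_runs(p, q)
                child_sel = solve_child(child)
                token = PlaceholderToken()
                # infixes have >= 2 runs, so the child optimum is positive
                new_pairs.append((token, child_sel.total_length))
                new_prov.append(SolvedInfix(prov[p - 1 : q], child_sel, token))
                cursor = q + 1
            for k in range(cursor, rs.n + 1):
                new_pairs.append(rs.pairs()[k - 1])
                new_prov.append(prov[k - 1])
            outer = RunString.from_pairs(new_pairs)
            return _decompose(outer, tuple(new_prov), solve_child, use_prefix, use_infix)
    return Leaf(rs, prov)


def leaves(tree: ReductionTree) -> list[Leaf]:
    """Leaves in depth-first (string) order."""
    if isinstance(tree, Leaf):
        return [tree]
    out: list[Leaf] = []
    for child in tree.children:
        out.extend(leaves(child))
    return out


def _expand_prov(entry: Prov) -> list[int]:
    if isinstance(entry, Original):
        return [entry.index]
    out: list[int] = []
    for li in entry.selection.indices:
        out.extend(_expand_prov(entry.prov[li - 1]))
    return out


def reassemble(
    tree: ReductionTree,
    leaf_solutions: Sequence[Selection],
    original: RunString,
) -> Selection:
    """Stitch per-leaf optima into a selection on the original instance.

    ``leaf_solutions`` must be parallel to :func:`leaves`.  A selected
    placeholder run contributes its child's selected runs; a dropped
    placeholder contributes nothing.  The result is optimal whenever all
    child and leaf solutions are.
    """
    tree_leaves = leaves(tree)
    if len(tree_leaves) != len(leaf_solutions):
        raise LRSError(
            f"expected {len(tree_leaves)} leaf solutions, got {len(leaf_solutions)}"
        )
    indices: list[int] = []
    for leaf, sel in zip(tree_leaves, leaf_solutions):
        if sel.indices and max(sel.indices) > leaf.instance.n:
            raise LRSError("leaf solution does not match leaf instance")
        for li in sel.indices:
            indices.extend(_expand_prov(leaf.prov[li - 1]))
    return make_selection(original, sorted(indices))


def tree_as_dict(tree: ReductionTree) -> dict:
    """JSON-friendly view of a decomposition (for the debug CLI)."""
    if isinstance(tree, Concat):
        return {"kind": "prefix-split", "children": [tree_as_dict(c) for c in tree.children]}
    placeholder_map = {}
    for entry in tree.prov:
        if isinstance(entry, SolvedInfix):
            placeholder_map[repr(entry.symbol)] = {
                "optimum": entry.selection.total_length,
                "runs": len(entry.prov),
            }
    return {
        "kind": "leaf",
        "runs": [[str(r.symbol), r.length] for r in tree.instance.runs],
        "placeholders": placeholder_map,
    }
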