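"""Run-length instance model for the longest run subsequence (LRS) problem.

A *run* is a maximal block of identical consecutive symbols.  An LRS
instance is a string over a finite alphabet, stored in run-length form:
the string ``b1 b1 b4 b4 b4 ...`` becomes the run sequence
``(b1,2)(b4,3)...``.  A *run subsequence* is a subsequence of the string
whose induced sequence contains at most one maximal run per symbol; the
LRS problem asks for the longest one.  Because it is always at least as
good to take a run entirely or not at all, solvers operate on whole runs.

Run indices are 1-based throughout; index 0 is reserved for the dynamic
program's virtual start vertex.  Symbols are arbitrary hashable tokens
(in the scaffolding application they are contig names), not only single
characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

Token = Hashable


class LRSError(Exception):
    """Base class for usage errors raised by this package."""


@dataclass(frozen=True)
class Run:
    """A maximal block of ``length`` consecutive copies of ``symbol``.

    ``start`` is the 1-based position of the run's first character in the
    expanded string.
    """

    symbol: Token
    length: int
    start: int = 1

    def __post_init__(self) -> None:
        if self.length < 1:
            raise LRSError(f"run length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class RunString:
    """An LRS instance: ordered maximal runs plus derived metadata.

    Attributes
    ----------
    runs:
        Tuple of :class:`Run`, indexed 1..n through :meth:`run`.
    alphabet:
        The set of symbols actually occurring.
    m:
        Expanded string length (sum of run lengths).
    """

    runs: tuple[Run, ...]
    alphabet: frozenset = field(init=False)
    m: int = field(init=False)

    def __post_init__(self) -> None:
        for a, b in zip(self.runs, self.runs[1:]):
            if a.symbol == b.symbol:
                raise LRSError(
                    f"adjacent runs share symbol {a.symbol!r}: runs are not maximal"
                )
        object.__setattr__(self, "alphabet", frozenset(r.symbol for r in self.runs))
        object.__setattr__(self, "m", sum(r.length for r in self.runs))

    @property
    def n(self) -> int:
        """Number of runs."""
        return len(self.runs)

    def run(self, i: int) -> Run:
        """Return run ``i`` (1-based)."""
        if not 1 <= i <= self.n:
            raise LRSError(f"run index {i} out of range 1..{self.n}")
        return self.runs[i - 1]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[Token, int]]) -> "RunString":
        """Build an instance from ``(symbol, length)`` pairs, computing starts."""
        runs = []
        pos = 1
        for sym, length in pairs:
            runs.append(Run(sym, length, pos))
            pos += length
        return cls(tuple(runs))

    def pairs(self) -> tuple[tuple[Token, int], ...]:
        return tuple((r.symbol, r.length) for r in self.runs)

    def slice_runs(self, p: int, q: int) -> "RunString":
        """Sub-instance of runs ``p..q`` (1-based, inclusive)."""
        if not (1 <= p <= q <= self.n):
            raise LRSError(f"invalid run slice [{p},{q}] for n={self.n}")
        return RunString.from_pairs(self.pairs()[p - 1 : q])

    def __repr__(self) -> str:  # compact, e.g. (b1^2)(b4^3)
        body = "".join(f"({r.symbol}^{r.length})" for r in self.runs)
        return f"RunString[{body or 'empty'}]"


@dataclass(frozen=True)
class Selection:
    """A set of chosen run indices with derived score and induced subsequence."""

    indices: tuple[int, ...]
    total_length: int
    subsequence: tuple[Token, ...]


def compress(tokens: Sequence[Token]) -> RunString:
    """Run-length compress a token sequence into a :class:`RunString`.

    The empty sequence yields the empty instance (n = 0, m = 0).
    """
    pairs: list[tuple[Token, int]] = []
    for t in tokens:
        if pairs and pairs[-1][0] == t:
            pairs[-1] = (t, pairs[-1][1] + 1)
        else:
            pairs.append((t, 1))
    return RunString.from_pairs(pairs)


def expand(rs: RunString) -> tuple[Token, ...]:
    """Inverse of :func:`compress`: the full token sequence of the instance."""
    out: list[Token] = []
    for r in rs.runs:
        out.extend([r.symbol] * r.length)
    return tuple(out)


def last_occurrence(rs: RunString, sigma: Token, i: int) -> int:
    """Index of the last run before run ``i`` with symbol ``sigma`` (0 if none).

    This is the P_sigma(i) index function: the largest j < i with
    sigma(r_j) = sigma.  ``sigma`` need not occur in the instance.
    """
    if not 1 <= i <= rs.n:
        raise LRSError(f"run index {i} out of range 1..{rs.n}")
    for j in range(i - 1, 0, -1):
        if rs.runs[j - 1].symbol == sigma:
            return j
    return 0


def predecessor_set(rs: RunString, i: int) -> frozenset[int]:
    """Candidate predecessor run indices for run ``i`` in the dynamic program.

    The set contains P_sigma(i) for every symbol sigma (plus a virtual-start
    pseudo-symbol with P = 0 everywhere) whose value is at least
    P_{sigma(r_i)}(i).  Hence 0 is a member iff sigma(r_i) does not occur
    before run i.  Size is at most |alphabet| + 1.
    """
    if not 1 <= i <= rs.n:
        raise LRSError(f"run index {i} out of range 1..{rs.n}")
    last: dict[Token, int] = {}
    for j in range(1, i):
        last[rs.runs[j - 1].symbol] = j
    threshold = last.get(rs.runs[i - 1].symbol, 0)
    preds = {p for p in last.values() if p >= threshold}
    if threshold == 0:
        preds.add(0)
    return frozenset(preds)


def is_valid_selection(rs: RunString, sel: Selection) -> bool:
    """True iff the selected runs induce at most one maximal run per symbol.

    Selected same-symbol runs separated only by unselected runs merge into a
    single run and are legal.  Runs in one linear scan over the selection,
    tracking which symbols have been closed off.
    """
    _check_indices(rs, sel.indices)
    closed: set[Token] = set()
    prev: Token | None = None
    for i in sel.indices:
        sym = rs.runs[i - 1].symbol
        if sym != prev:
            if sym in closed:
                return False
            if prev is not None:
                closed.add(prev)
            prev = sym
    return True


def selection_length(rs: RunString, sel: Selection) -> int:
    """Objective value: total expanded length of the selected runs."""
    _check_indices(rs, sel.indices)
    return sum(rs.runs[i - 1].length for i in sel.indices)


def make_selection(rs: RunString, indices: Iterable[int]) -> Selection:
    """Construct a :class:`Selection` with derived fields from run indices."""
    idx = tuple(indices)
    _check_indices(rs, idx)
    total = sum(rs.runs[i - 1].length for i in idx)
    seq: list[Token] = []
    for i in idx:
        r = rs.runs[i - 1]
        seq.extend([r.symbol] * r.length)
    return Selection(idx, total, tuple(seq))


def _check_indices(rs: RunString, indices: Sequence[int]) -> None:
    prev = 0
    for i in indices:
        if not 1 <= i <= rs.n:
            raise LRSError(f"selected run index {i} out of range 1..{rs.n}")
        if i <= prev:
            raise LRSError("selected run indices must be strictly increasing")
        prev = i
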