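"""Exact dynamic program over (run index, used-symbol subset).

``D[i, F]`` is the best total length of a run subsequence of runs 1..i that
selects run i itself and uses exactly the symbols in F.  Each run's
candidate predecessors are the last occurrences of every symbol at or after
the last earlier occurrence of the run's own symbol (the predecessor set of
:func:`lrskit.runstring.predecessor_set`), plus the virtual start vertex 0
when the run is the first of its symbol.  A same-symbol predecessor extends
the run without consuming a new symbol; a different-symbol predecessor adds
the run's symbol to F.

Worst-case cost is O(|Sigma| * n * 2^|Sigma|) time, making this fixed
parameter tractable in the alphabet size.  The table is held sparsely,
column by column, keeping only reachable subsets; memory, not time, is the
practical wall for large alphabets, hence the configurable alphabet cap.

Symbol subsets are bitmasks over a dense per-instance symbol indexing (order
of first occurrence).  Ties are broken deterministically: among predecessors
attaining the maximum the smallest index wins, and among globally optimal
table entries the smallest run index, then the numerically smallest mask.
"""

from __future__ import annotations

from .runstring import LRSError, RunString, Selection, make_selection

DEFAULT_ALPHABET_CAP = 25


class AlphabetTooLargeError(LRSError):
    """Raised when the instance alphabet exceeds the DP's configured cap."""


def solve_dp(rs: RunString, alphabet_cap: int = DEFAULT_ALPHABET_CAP) -> Selection:
    """Optimal valid selection via subset DP with backtracking.

    Raises :class:`AlphabetTooLargeError` when ``|alphabet| > alphabet_cap``
    (the caller should fall back to the ILP, which is insensitive to
    alphabet size).
    """
    n = rs.n
    if n == 0:
        return make_selection(rs, ())
    sigma = len(rs.alphabet)
    if sigma > alphabet_cap:
        raise AlphabetTooLargeError(
            f"alphabet too large for DP: {sigma} symbols exceeds cap {alphabet_cap}"
        )

    sym_bit: dict = {}
    for r in rs.runs:  # dense bit per symbol, first-occurrence order
        if r.symbol not in sym_bit:
            sym_bit[r.symbol] = 1 << len(sym_bit)

    symbols = [r.symbol for r in rs.runs]
    lengths = [r.length for r in rs.runs]

    # columns[i]: mask -> (value, (pred_index, pred_mask)); column 0 is the
    # virtual start (empty prefix, empty subset).
    columns: list[dict[int, tuple[int, tuple[int, int] | None]]] = [
        {0: (0, None)}
    ]
    last_occ: dict = {}  # symbol -> last run index seen so far

    for i in range(1, n + 1):
        sym = symbols[i - 1]
        bit = sym_bit[sym]
        length = lengths[i - 1]
        threshold = last_occ.get(sym, 0)
        preds = sorted(p for p in last_occ.values() if p >= threshold)
        if threshold == 0:
            preds.insert(0, 0)

        entries: dict[int, tuple[int, tuple[int, int] | None]] = {}
        for j in preds:  # ascending: smallest predecessor wins ties
            same = j > 0 and symbols[j - 1] == sym
            for mask_j, (val, _) in columns[j].items():
                if same:
                    new_mask = mask_j  # symbol already in F
                else:
                    if mask_j & bit:
                        continue  # F must not already contain the new symbol
                    new_mask = mask_j | bit
                cand = val + length
                cur = entries.get(new_mask)
                if cur is None or cand > cur[0]:
                    entries[new_mask] = (cand, (j, mask_j))
        columns.append(entries)
        last_occ[sym] = i

    best_val = 0
    best_key: tuple[int, int] | None = None
    for i in range(1, n + 1):
        for mask in sorted(columns[i]):
            val = columns[i][mask][0]
            if val > best_val:
                best_val = val
                best_key = (i, mask)

    if best_key is None:
        return make_selection(rs, ())

    indices: list[int] = []
    i, mask = best_key
    while i > 0:
        indices.append(i)
        _, back = columns[i][mask]
        assert back is not None
        i, mask = back
    indices.reverse()
    return make_selection(rs, indices)
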