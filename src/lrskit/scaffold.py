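"""Homology-scaffolding adapter: alignments -> per-contig LRS instances.

Given alignments between two contig sets A and B, each A-contig is divided
into fixed-size bins (default 10 kb, a size that balances positional
resolution against instance complexity).  Each bin is assigned the B-contig
with the most aligned bases overlapping it; the per-bin assignments, read
in bin order, form a string over the B-contig alphabet.  Solving LRS on
that string yields the longest sub-sequence with one contiguous block per
B-contig — an ordering of (a subset of) the B-contigs along the A-contig —
while the dropped bins are the ones in conflict with that order (mismapped
bins, repeats, rearrangements).

Conventions: coordinates are 0-based half-open; bin k of a contig of length
L covers [k*bin_size, min((k+1)*bin_size, L)) and the final short bin is
kept.  Strands are pooled when counting aligned bases: an inversion inside
a single contig does not change which contig a bin belongs to, so it should
not affect the ordering.  Bins with no alignment are omitted from the
string rather than given a private symbol — a symbol occurring once would
always be selected and could never constrain the order, it would only
inflate the instance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .runstring import LRSError, compress
from .solver_api import SolveOptions, solve

DEFAULT_BIN_SIZE = 10_000


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise alignment (PAF semantics; query = A-contig, target = B)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alen: int
    mapq: int

    def __post_init__(self) -> None:
        for label, start, end, length in (
            ("query", self.qstart, self.qend, self.qlen),
            ("target", self.tstart, self.tend, self.tlen),
        ):
            if not 0 <= start < end <= length:
                raise LRSError(
                    f"invalid {label} interval [{start}, {end}) for length {length}"
                )


@dataclass(frozen=True)
class BinAssignment:
    """Per-bin best-match assignments for one A-contig.

    ``bins[k]`` is ``(b_contig, aligned_bases)`` or ``None`` for a bin with
    no alignment; ``len(bins) == ceil(contig length / bin_size)``.
    """

    contig: str
    bin_size: int
    bins: tuple[Optional[tuple[str, int]], ...]

    @property
    def assigned_bins(self) -> tuple[int, ...]:
        return tuple(k for k, b in enumerate(self.bins) if b is not None)


@dataclass(frozen=True)
class ContigOrder:
    """LRS-derived ordering of B-contigs along one A-contig."""

    contig: str
    order: tuple[str, ...]  # distinct B-contigs, in inferred order
    support: dict = field(default_factory=dict)  # b_contig -> supporting bin count
    conflicting_bins: tuple[int, ...] = ()  # assigned bins dropped by LRS
    n_assigned: int = 0
    optimum: int = 0


def read_alignments(source, dialect: str = "paf") -> list[AlignmentRecord]:
    """Parse PAF alignment records (>= 12 mandatory columns).

    ``source`` is a path or an iterable of lines.  Malformed lines raise
    with their line number.
    """
    if dialect != "paf":
        raise LRSError(f"unsupported alignment dialect {dialect!r}")
    if isinstance(source, str):
        with open(source) as fh:
            return read_alignments(fh)
    records = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise LRSError(f"PAF line {lineno}: expected >= 12 columns, got {len(cols)}")
        try:
            rec = AlignmentRecord(
                qname=cols[0],
                qlen=int(cols[1]),
                qstart=int(cols[2]),
                qend=int(cols[3]),
                strand=cols[4],
                tname=cols[5],
                tlen=int(cols[6]),
                tstart=int(cols[7]),
                tend=int(cols[8]),
                nmatch=int(cols[9]),
                alen=int(cols[10]),
                mapq=int(cols[11]),
            )
        except (ValueError, LRSError) as exc:
            raise LRSError(f"PAF line {lineno}: {exc}") from exc
        if rec.strand not in "+-":
            raise LRSError(f"PAF line {lineno}: strand must be + or -, got {rec.strand!r}")
        records.append(rec)
    return records


def assign_bins(
    records: Iterable[AlignmentRecord],
    a_lengths: dict,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> dict[str, BinAssignment]:
    """Best-matching B-contig per bin for every A-contig.

    For each bin, aligned bases are the overlap (in query coordinates) of
    each record with the bin window, summed per B-contig across records and
    strands.  The argmax B-contig wins; ties go to the lexicographically
    smaller contig id; bins without overlap stay unassigned.
    """
    if bin_size < 1:
        raise LRSError("bin_size must be >= 1")
    # (a_contig, bin index) -> {b_contig: bases}
    tallies: dict[tuple[str, int], dict[str, int]] = {}
    for rec in records:
        if rec.qname not in a_lengths:
            raise LRSError(f"record references unknown A-contig {rec.qname!r}")
        if rec.qlen != a_lengths[rec.qname]:
            raise LRSError(
                f"length mismatch for {rec.qname!r}: record says {rec.qlen}, "
                f"lengths table says {a_lengths[rec.qname]}"
            )
        first_bin = rec.qstart // bin_size
        last_bin = (rec.qend - 1) // bin_size
        for k in range(first_bin, last_bin + 1):
            lo = max(rec.qstart, k * bin_size)
            hi = min(rec.qend, (k + 1) * bin_size)
            if hi > lo:
                bucket = tallies.setdefault((rec.qname, k), {})
                bucket[rec.tname] = bucket.get(rec.tname, 0) + (hi - lo)

    out: dict[str, BinAssignment] = {}
    for contig, length in a_lengths.items():
        n_bins = -(-length // bin_size)  # ceil
        bins: list[Optional[tuple[str, int]]] = []
        for k in range(n_bins):
            bucket = tallies.get((contig, k))
            if not bucket:
                bins.append(None)
            else:
                best = max(bucket.items(), key=lambda kv: (kv[1], _neg_lex(kv[0])))
                bins.append(best)
        out[contig] = BinAssignment(contig, bin_size, tuple(bins))
    return out


def _neg_lex(name: str):
    # invert lexicographic order so max() prefers the smaller id on base ties
    return tuple(-ord(c) for c in name)


def read_assignments_tsv(source, bin_size: int = DEFAULT_BIN_SIZE) -> dict[str, BinAssignment]:
    """Read precomputed assignments: ``a_contig  bin_index  b_contig  aligned_bases``."""
    if isinstance(source, str):
        with open(source) as fh:
            return read_assignments_tsv(fh, bin_size)
    per_contig: dict[str, dict[int, tuple[str, int]]] = {}
    for lineno, row in enumerate(csv.reader(source, delimiter="\t"), start=1):
        if not row or row[0].startswith("#"):
            continue
        if len(row) != 4:
            raise LRSError(f"assignments line {lineno}: expected 4 columns, got {len(row)}")
        a, k, b, bases = row[0], int(row[1]), row[2], int(row[3])
        per_contig.setdefault(a, {})[k] = (b, bases)
    out = {}
    for contig, entries in per_contig.items():
        n_bins = max(entries) + 1
        bins = tuple(entries.get(k) for k in range(n_bins))
        out[contig] = BinAssignment(contig, bin_size, bins)
    return out


def order_contigs(ba: BinAssignment, opts: SolveOptions | None = None) -> ContigOrder:
    """Solve LRS on the bin string and read off the B-contig order.

    The token sequence is the assigned B-contig per bin, in bin order
    (unassigned bins omitted).  Selected runs give the contig order and
    per-contig supporting bin counts; assigned bins not covered by the
    selection are the conflicting bins.
    """
    assigned = ba.assigned_bins
    if not assigned:
        raise LRSError(f"contig {ba.contig!r} has no assigned bins")
    tokens = [ba.bins[k][0] for k in assigned]
    rs = compress(tokens)
    result = solve(rs, opts)

    # map selected runs back to bin indices
    run_spans: list[tuple[int, int]] = []  # token-position span per run, 0-based
    pos = 0
    for r in rs.runs:
        run_spans.append((pos, pos + r.length))
        pos += r.length
    selected_positions: set[int] = set()
    order: list[str] = []
    support: dict[str, int] = {}
    for i in result.selection.indices:
        lo, hi = run_spans[i - 1]
        selected_positions.update(range(lo, hi))
        sym = rs.runs[i - 1].symbol
        if not order or order[-1] != sym:
            order.append(sym)
        support[sym] = support.get(sym, 0) + (hi - lo)
    conflicts = tuple(
        assigned[p] for p in range(len(assigned)) if p not in selected_positions
    )
    return ContigOrder(
        contig=ba.contig,
        order=tuple(order),
        support=support,
        conflicting_bins=conflicts,
        n_assigned=len(assigned),
        optimum=result.optimum,
    )
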