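"""Plain-text instance formats.

Two dialects, one instance per line, ``#`` starts a comment line:

``chars``
    every character of the line is one token (classic string instances);
``tokens``
    whitespace-separated tokens (contig names, multi-character symbols).
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .runstring import LRSError, RunString, compress

DIALECTS = ("chars", "tokens")


def parse_instances(lines: Iterable[str], dialect: str = "chars") -> list[list[str]]:
    """Parse instance lines into token lists, skipping comments and blanks."""
    if dialect not in DIALECTS:
        raise LRSError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    out: list[list[str]] = []
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if dialect == "chars":
            out.append(list(line.strip()))
        else:
            out.append(line.split())
    return out


def read_instances(path: str, dialect: str = "chars") -> list[RunString]:
    """Read and run-length compress all instances in a file."""
    with open(path) as fh:
        return [compress(toks) for toks in parse_instances(fh, dialect)]


def format_instance(tokens: Sequence[str], dialect: str = "chars") -> str:
    if dialect == "chars":
        bad = [t for t in tokens if len(str(t)) != 1]
        if bad:
            raise LRSError(f"chars dialect needs single-character tokens, got {bad[:3]}")
        return "".join(str(t) for t in tokens)
    return " ".join(str(t) for t in tokens)


def format_run_encoded(rs: RunString) -> str:
    """One-line run encoding ``sym^len sym^len ...`` (tokens dialect with lengths).

    Used for instances whose expansion would be impractically large, e.g. the
    hardness construction where run lengths are in the millions.
    """
    return " ".join(f"{r.symbol}^{r.length}" for r in rs.runs)


def parse_run_encoded(line: str) -> RunString:
    """Inverse of :func:`format_run_encoded`."""
    pairs = []
    for tok in line.split():
        sym, _, length = tok.rpartition("^")
        if not sym or not length.isdigit():
            raise LRSError(f"bad run token {tok!r}; expected sym^len")
        pairs.append((sym, int(length)))
    return RunString.from_pairs(pairs)
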