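"""Synthetic LRS-instance generators.

Two regimes:

* :func:`random_instance` — uniform i.i.d. strings over an s-symbol
  alphabet, redrawn wholesale until every symbol occurs.  These are
  worst-case inputs for the reduction rules (short runs, no locality) and
  drive the solver cross-validation experiments.
* :func:`planted_instance` — pre-sorted segment structure with substitution
  noise, emulating real scaffolding instances: a binned contig is mostly a
  sequence of long same-contig blocks, interrupted by occasional mismapped
  bins.  The planted segment order is returned as ground truth for
  order-recovery tests.

All generators are deterministic given their seed and draw from one local
``numpy`` generator per call (no global RNG state).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .runstring import LRSError, RunString, compress

MAX_REJECTION_RETRIES = 1000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted-structure generator.

    ``segments`` planted blocks of fresh symbols laid out in order; each
    block's length is Poisson-distributed around ``mean_run_length`` (min 1);
    afterwards every position is independently replaced by a uniformly
    random *other* symbol with probability ``noise_rate``.
    """

    segments: int = 5
    mean_run_length: float = 50.0
    noise_rate: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate < 1.0:
            raise LRSError(f"noise_rate must be in [0, 1), got {self.noise_rate}")
        if self.segments < 1:
            raise LRSError("need at least one segment")


def alphabet_tokens(s: int) -> list[str]:
    """The canonical synthetic alphabet: tokens ``s1 .. s<s>``."""
    return [f"s{i}" for i in range(1, s + 1)]


def random_instance(m: int, s: int, seed: Optional[int] = None) -> RunString:
    """Uniform random string of length ``m`` guaranteed to use all ``s`` symbols.

    The guarantee is enforced by whole-string rejection sampling (redraw the
    entire string until all symbols occur) so the accepted string's local
    structure stays that of a uniform i.i.d. draw.  Raises after
    ``MAX_REJECTION_RETRIES`` failed draws (possible only for pathological
    m barely >= s configurations).
    """
    if s < 1:
        raise LRSError("alphabet size must be >= 1")
    if m < s:
        raise LRSError(f"length m={m} cannot cover alphabet size s={s}")
    rng = np.random.default_rng(seed)
    tokens = alphabet_tokens(s)
    for _ in range(MAX_REJECTION_RETRIES):
        draw = rng.integers(0, s, size=m)
        if len(np.unique(draw)) == s:
            return compress([tokens[k] for k in draw])
    raise LRSError(
        f"rejection sampling failed to cover the alphabet in "
        f"{MAX_REJECTION_RETRIES} draws (m={m}, s={s})"
    )


def planted_instance(config: SimConfig) -> tuple[RunString, tuple[str, ...]]:
    """Planted segment structure with substitution noise.

    Returns ``(instance, planted_order)`` where ``planted_order`` is the
    left-to-right sequence of segment symbols (the ground-truth contig
    order).  With zero noise the LRS optimum equals the full string length
    and the recovered order equals the planted one.
    """
    rng = np.random.default_rng(config.seed)
    symbols = [f"b{i}" for i in range(1, config.segments + 1)]
    tokens: list[str] = []
    for sym in symbols:
        length = max(1, int(rng.poisson(config.mean_run_length)))
        tokens.extend([sym] * length)
    if config.noise_rate > 0 and config.segments > 1:
        for pos in range(len(tokens)):
            if rng.random() < config.noise_rate:
                others = [s for s in symbols if s != tokens[pos]]
                tokens[pos] = others[rng.integers(0, len(others))]
    return compress(tokens), tuple(symbols)


def recovered_order(selection_subsequence: Sequence) -> tuple:
    """Distinct symbols of a solved selection's subsequence, in run order."""
    order: list = []
    for t in selection_subsequence:
        if not order or order[-1] != t:
            order.append(t)
    return tuple(order)
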