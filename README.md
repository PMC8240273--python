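# lrskit

Exact solvers for the **longest run subsequence (LRS)** problem, with an
adapter for homology-based contig ordering in genome scaffolding.

## The problem

A *run* is a maximal block of identical consecutive symbols.  Given a
string `S = s_1 … s_m` over a finite alphabet `Σ`, a *run subsequence* is a
subsequence `S′` containing at most one maximal run per symbol: for every
pair of positions `i < j` in `S′`,

```
s′_i = s′_j  ⇒  s′_l = s′_i   for all i < l < j.
```

LRS asks for the longest such subsequence.  Because it never pays to take a
run partially, the problem lives on the run-length encoding
`σ(r_1)^{L(r_1)} … σ(r_n)^{L(r_n)}`.

Why care: when two incomplete assemblies of related samples are mapped
against each other, each contig of assembly A can be cut into fixed-size
bins and every bin labelled with its best-matching contig of assembly B.
The resulting string should decompose into one contiguous block per
B-contig — but mismapped bins break it up.  LRS finds the longest
one-block-per-contig partition; its run order is an ordering of the
B-contigs, and the dropped characters are the conflicting bins.  The
problem is NP-hard (reduction from the linear ordering problem, shipped
here as a self-verifying harness), yet realistic instances solve in
milliseconds after reduction.

## What is in the box

| module | contents |
| --- | --- |
| `lrskit.runstring` | run-length model, the `P_σ(i)` last-occurrence index machinery, selection validity/scoring |
| `lrskit.reduce` | optimum-preserving prefix/infix decomposition and reassembly |
| `lrskit.dp_solver` | subset dynamic program `D[i, F]`, `O(|Σ|·n·2^{|Σ|})` — FPT in alphabet size |
| `lrskit.ilp_solver` | 0/1 ILP over runs (two equivalent constraint families, ≤ ⌈n/2⌉² constraints) behind an abstract MIP-backend contract (default: HiGHS via SciPy) |
| `lrskit.oracle` | brute-force reference solver for testing |
| `lrskit.solver_api` | `solve()`: shortcuts → reductions → hybrid DP/ILP dispatch → reassembly |
| `lrskit.lop_hardness` | the NP-hardness construction as generator + theorem-checking harness |
| `lrskit.scaffold` | PAF parsing, 10 kb binning, best-match assignment, contig ordering |
| `lrskit.simulate` | random full-alphabet instances and planted-order instances |

## Worked example

```python
from lrskit import compress, solve

tokens = (["b1"]*2 + ["b4"]*3 + ["b1"]*3 + ["b3"]*3
          + ["b1"] + ["b3"] + ["b2"]*3 + ["b3"])
res = solve(compress(tokens))
print(res.optimum, res.selection.indices, res.dropped)
```

prints

```
13 (2, 3, 4, 6, 7) (1, 5, 8)
```

The 17-character string compresses to `b1² b4³ b1³ b3³ b1¹ b3¹ b2³ b3¹`;
the optimum keeps 13 characters (`b4³ b1³ b3³⁺¹ b2³` — the two selected
`b3` runs merge because only an unselected run lies between them), which
orders the contigs `b4, b1, b3, b2` and flags the 4 remaining bins as
conflicts.  `examples/` contains one narrative script per capability
(solving, reductions, the hardness harness, contig ordering, noisy
recovery), each printing the numbers it computes.

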