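# Methods

## Model

An LRS instance is a string over a finite alphabet, stored as its unique
maximal-run decomposition `r_1 … r_n` with symbols `σ(r_i)` and lengths
`L(r_i)`.  A feasible solution is a set of run indices whose induced
subsequence has at most one maximal run per symbol; same-symbol runs
separated only by *unselected* runs merge and are feasible.  The objective
is the total selected length.  Working on runs rather than characters is
itself an exact reduction: any optimum takes runs wholly or not at all,
since a partially taken run can always be completed without creating a new
run of its symbol.

Indices are 1-based; 0 denotes the dynamic program's virtual start vertex.
Symbols are arbitrary hashable tokens (contig names in the scaffolding
application); the single-character `chars` text dialect is a parsing
convenience, not a core restriction.  Empty instances are legal everywhere
with optimum 0.

## Reduction rules

*Prefix rule.*  If runs `1..p` use an alphabet disjoint from runs
`p+1..n`, the two sides cannot interact and optima concatenate.  The
shortest independent prefix is found by one left-to-right sweep that keeps
the maximum last-occurrence index of the symbols seen so far; the rule is
iterated, so the instance falls apart into maximal independent pieces.

*Infix rule.*  An infix with an exclusive alphabet contributes either
nothing or its own optimum to any solution through it.  It is solved
recursively and replaced by a single placeholder run whose length is the
infix optimum.  Candidate infixes are grown from each anchor symbol's
first/last occurrence to an alphabet-closed fixed point; closed proper
intervals are collected, overlapping/nested/adjacent intervals merged, and
single-run intervals discarded (they reduce nothing).  Merging runs before
the single-run filter, so two adjacent single-run candidates still yield a
usable two-run reduction.  A merged interval that ends up covering the
whole string is dropped; the prefix rule handles that split.

Placeholder symbols are identity-compared sentinel objects, so they can
never collide with input tokens.  Orchestration: exhaust the prefix rule,
find infixes on each piece, recurse into each infix (starting again with
the prefix rule), substitute, and decompose the substituted instance
again.  Recursion strictly shrinks the run count, so depth is bounded
by `n`.

The decomposition record is a tree of concatenation nodes and irreducible
leaves; each leaf run carries a provenance entry — an original run index,
or a solved placeholder holding the replaced child's provenance and local
selection.  Reassembly expands selected provenance entries recursively,
which is exactly the information needed to splice child optima back into
a selection over the original instance.  (An explicit infix-split node
kind would carry the same information; the flattened form keeps reassembly
a single tree walk.)

## Exact algorithms

*Subset DP.*  `D[i, F]` is the best length of a run subsequence of
`r_1 … r_i` that selects `r_i` and uses exactly the symbols of `F ⊆ Σ`.
Candidate predecessors of run `i` are the last occurrences `P_σ(i)` of all
symbols at or after `P_{σ(r_i)}(i)` — any earlier predecessor would leave
an interposed run of `σ(r_i)` that a better solution would include — plus
the virtual start when `i` is the first of its symbol.  We keep this
predecessor definition exactly as stated (solutions starting at a later
same-symbol run are dominated, not enumerated) and validate against the
brute-force oracle.  Subsets are bitmasks over a dense first-occurrence
symbol indexing; the table is materialized sparsely column by column,
holding only reachable subsets, because memory rather than time is the
practical wall on large alphabets.  The alphabet cap defaults to 25
symbols; beyond it the solver raises and the dispatcher uses the ILP.
Values are exact integers; missing entries stand for −∞.  Tie-breaks are
deterministic: smallest predecessor index, then smallest run index, then
numerically smallest mask.

*ILP.*  One binary `x_i` per run, objective `max Σ x_i L(r_i)`.  For every
same-symbol pair `i < j`, either the per-run family `x_l ≤ 2 − x_i − x_j`
(for each different-symbol `l` strictly between) or the aggregated family
`Σ x_l ≤ (j − i)(2 − x_i − x_j)` — one row per pair, at most `⌈n/2⌉²`
rows.  The aggregated family is the default; both are kept and tested
equivalent.  Models are built in deterministic order.  The solver sits
behind a minimal backend contract (binary variables, linear rows, proof of
optimality); the default adapter is HiGHS branch-and-bound through
`scipy.optimize.milp`, run with a zero MIP gap — the hardness instances
have objective coefficients around 10⁵, where a relative-gap stop could
return a value a few units below the true optimum.  Only proven optima are
accepted; variable values above 0.5 decode as selected.  LP-format export
is available for debugging.

*Brute force.*  Include-first depth-first search over run subsets with
incremental validity and a remaining-length bound; enumeration order makes
the returned optimum the lexicographically smallest index set.  Capped at
22 runs.  It shares `is_valid_selection` with everything else, so the
problem definition exists in one place.

*Hybrid dispatch.*  Per irreducible leaf (the instances solvers actually
see), the ILP is chosen iff `m < 10 (|Σ| − 13)`, the DP otherwise; the
constants are configurable, and the size measure can be switched from
expanded length `m` to run count `n` (default `m`).  Leaves with at most
one run, or one run per symbol, are taken wholesale without any solver —
on real scaffolding data the reductions leave mostly such trivial leaves,
where solver setup would dominate.

## Hardness harness

The linear ordering problem (LOP) — order the vertices of a complete
weighted digraph to maximize forward-edge weight — reduces to LRS.  With
`M′ = 4n²·w_sum` and `M = M′·n³`, the instance has per-vertex blocks of
edge blocks `E_{i,j}^{w_ij+w_sum} Δ…Δ E_{i,j}^{w_ij+w_sum}` (triangle runs
of length `M′`, `k` ascending) separated by `$_i^M`, and
`LRS(S) = f_G(k*) = (n−1)M + n(n−1)(n−2)/3·M′ + n(n−1)·w_sum + 2k*` where
`k*` is the LOP optimum.  Triangle signs are canonicalized to the
lexicographically smallest rotation of `(i,j,k)`.  Weights are first
shifted to be ≥ 1 (uniform offset, returned for translating objectives
back); `n < 3` is refused since the construction needs triangles.  The
harness solves small digraphs exhaustively (`n ≤ 8`), the constructed
strings with the DP for `n = 3` (7 occurring symbols) and the ILP for
`n = 4` (17 occurring symbols — note only `n − 1` of the `n` defined
separator symbols occur), and asserts equality; a provenance map from runs
to construction blocks lets the tests also check the structure of optima
(all separators selected, one run per triangle sign, exactly one fully
selected edge block per vertex pair).  Instances stay in run-length form;
expansion is refused above 10⁶ characters.

## Scaffolding adapter

PAF records (12+ mandatory columns; query = A-contig, target = B-contig)
are parsed with per-line validation.  Bins are 0-based half-open windows
of 10 000 bases by default (an empirical balance between positional
resolution and instance size); the final short bin is kept.  A bin's
aligned bases per B-contig are the query-coordinate overlaps of all
records, pooled across strands — an inversion inside one contig should not
change which contig a bin belongs to.  The argmax B-contig wins, ties
going to the lexicographically smaller id; bins with no alignment are
omitted from the LRS string rather than given private symbols (a
once-occurring symbol is always selectable and can only inflate the
instance, never constrain the order).  The LRS solution's run order is the
inferred B-contig order; assigned bins outside the selection are reported
as conflicts, and `conflicts = assigned − optimum` always.  Only
per-A-contig orders are produced; merging them into global
pseudo-chromosomes (with orientation) is out of scope.

## Synthetic data

`random_instance(m, s, seed)` draws uniform i.i.d. strings and redraws the
whole string until all `s` symbols occur (up to 1000 retries).  Rejection
keeps the accepted string's local structure unbiased, unlike forced symbol
placement; configurations with `m` barely ≥ `s` can exhaust the retry
budget and raise.  These strings are worst cases for the reductions: short
runs, no locality.  `planted_instance` emulates the structure of real
instances — `g` segments of fresh symbols in a fixed order, segment
lengths Poisson around a mean (min 1), then per-position substitution
noise to a uniformly random other symbol.  It returns the planted order as
ground truth.  What the planted generator does *not* model: inversions,
translocations between distant segments, ambiguous multi-contig bins, or
unassigned-bin gaps; recovery rates on it bound only the mismapped-bin
noise regime, not every failure mode of real assemblies.

## Test and verification sizes

The randomized suites use fixed seeds throughout: 200 instances
(`m ≤ 20`, `|Σ| ≤ 6`) for the three-way solver agreement, 100 instances
(`m ≤ 30`, `|Σ| ≤ 8`) for reduction soundness, 25 randomized checks each
for the two decomposition lemmas, 20 digraphs (`n ∈ {3, 4}`, weights 1–5)
for the hardness equivalence, and 100 seeded planted instances (5 segments
of ~50, 5% noise) for order recovery, asserted at ≥ 95% — sizes chosen to
exercise every code path at brute-force-checkable scale.

## Known limitations

- The DP's sparse columns delay but do not remove the `2^{|Σ|}` memory
  wall; alphabets near the cap can still be slow or large.
- The hybrid rule's constants (10, 13) are empirical defaults, not tuned
  per machine or backend.
- The ILP path requires a backend that proves optimality; there is no
  anytime/heuristic mode by design.
- Leaves are solved sequentially; determinism is preferred over
  parallelism.
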