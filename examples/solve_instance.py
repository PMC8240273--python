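"""Solve one LRS instance three independent ways.

The instance is the canonical binned-contig match string over four
B-contigs.  All three exact algorithms must agree on the optimum; the
hybrid front end additionally reports which algorithm each irreducible
leaf was dispatched to.
"""

from lrskit import compress, solve
from lrskit.dp_solver import solve_dp
from lrskit.ilp_solver import solve_ilp
from lrskit.oracle import solve_bruteforce

tokens = (
    ["b1"] * 2 + ["b4"] * 3 + ["b1"] * 3 + ["b3"] * 3
    + ["b1"] + ["b3"] + ["b2"] * 3 + ["b3"]
)
rs = compress(tokens)
print("instance:", rs)  # 8 runs, 17 characters, 4 symbols

for name, solver in [("brute force", solve_bruteforce), ("DP", solve_dp), ("ILP", solve_ilp)]:
    sel = solver(rs)
    print(f"{name:>11}: optimum {sel.total_length}, runs {sel.indices}")

res = solve(rs)
print("hybrid front end:", res.optimum, "selected", res.selection.indices,
      "dropped", res.dropped, "via", res.algorithms_used)
# The optimum 13 keeps runs 2,3,4,6,7 (b4^3 b1^3 b3^3+1 b2^3): the two b3
# runs merge because only the unselected b1 run lies between them.  The 4
# dropped characters are the bins in conflict with that partition.
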