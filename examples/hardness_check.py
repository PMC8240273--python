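"""The NP-hardness construction, verified end to end.

A random complete digraph on 4 vertices is reduced to an LRS instance (51
runs over a 17-symbol alphabet with run lengths up to ~10^5).  The LRS
optimum, found by the ILP, must equal f_G(k*) where k* is the exhaustive
linear-ordering optimum — the two problems are the same in disguise.
"""

from lrskit.ilp_solver import solve_ilp
from lrskit.lop_hardness import (
    CompleteDigraph,
    check_optimal_structure,
    orientation_from_selection,
    verify_theorem,
)

g = CompleteDigraph.random(4, lo=1, hi=5, seed=7)
rec = verify_theorem(g, solve_ilp)
hi = rec["instance"]
print(f"LOP optimum k* = {rec['lop_optimum']} at ordering {rec['lop_ordering']}")
print(f"LRS instance: {hi.instance.n} runs, alphabet {len(hi.instance.alphabet)}, "
      f"M = {hi.m_big}, M' = {hi.m_prime}")
print(f"LRS optimum {rec['lrs_optimum']} == f_G(k*) {rec['expected']}: {rec['match']}")

st = check_optimal_structure(hi, rec["selection"])
print("separator runs selected:", st["separators_selected"], "/", st["separators_expected"])
print("triangle signs selected once each:", all(c == 1 for c in st["triangle_counts"].values()))
print("edge orientation read off the optimum:", orientation_from_selection(hi, rec["selection"]))
# The selected edge blocks form an acyclic tournament whose forward weight
# is exactly k*: the optimum of the string problem encodes the optimum of
# the ordering problem.
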