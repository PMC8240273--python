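"""Watch the prefix and infix rules decompose an instance.

The string aabcddcbe first sheds the independent prefix a^2, then the
piece (b)(c)(d^2)(c)(b) closes before (e) and is split off; inside it the
infix (c)(d^2)(c) uses an exclusive alphabet, is solved on its own
(optimum 3) and replaced by a placeholder run of length 3.
"""

import json

from lrskit import compress, solve
from lrskit.reduce import decompose, leaves, tree_as_dict

rs = compress("aabcddcbe")
tree = decompose(rs, solve_child=lambda sub: solve(sub).selection)
print(json.dumps(tree_as_dict(tree), indent=2))
print("leaves:", [leaf.instance.pairs() for leaf in leaves(tree)])

res = solve(rs)
print("optimum with reductions:", res.optimum, "leaf count:", res.leaf_count)
# Every leaf here is trivial (one run per symbol), so no DP/ILP call is
# needed at all — exactly what happens on real, mostly pre-sorted
# scaffolding instances.
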