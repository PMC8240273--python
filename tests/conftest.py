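import pytest

from lrskit.runstring import compress

# the running example used throughout: a binned contig matching four
# B-contigs, which compresses to (b1,2)(b4,3)(b1,3)(b3,3)(b1,1)(b3,1)(b2,3)(b3,1)
WORKED_TOKENS = (
    ["b1"] * 2 + ["b4"] * 3 + ["b1"] * 3 + ["b3"] * 3
    + ["b1"] + ["b3"] + ["b2"] * 3 + ["b3"]
)
WORKED_RUNS = (
    ("b1", 2), ("b4", 3), ("b1", 3), ("b3", 3),
    ("b1", 1), ("b3", 1), ("b2", 3), ("b3", 1),
)
WORKED_OPTIMUM = 13  # cross-validated by brute force, DP and ILP


@pytest.fixture
def worked_rs():
    return compress(WORKED_TOKENS)
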