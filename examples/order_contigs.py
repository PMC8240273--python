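"""Order one assembly's contigs along another via binned best matches.

Three toy PAF records map A-contigs onto B-contigs.  Each A-contig is cut
into 10 kb bins, each bin assigned its best-matching B-contig by aligned
bases, and LRS on the per-bin string gives the longest partition with one
contiguous block per B-contig — the inferred B-contig order, with the
conflicting bins listed separately.
"""

from lrskit.scaffold import BinAssignment, assign_bins, order_contigs, read_alignments

paf = [
    # qname qlen qstart qend strand tname tlen tstart tend nmatch alen mapq
    "A1\t25000\t0\t25000\t+\tB1\t30000\t0\t25000\t24000\t25000\t60",
    "A1\t25000\t0\t6000\t-\tB2\t9000\t0\t6000\t5000\t6000\t60",
    "A2\t12000\t2000\t9000\t+\tB3\t15000\t100\t7100\t6500\t7000\t60",
]
records = read_alignments(paf)
assignments = assign_bins(records, {"A1": 25000, "A2": 12000}, bin_size=10_000)
for contig, ba in sorted(assignments.items()):
    print(contig, "bins:", ba.bins)

co = order_contigs(assignments["A1"])
print("A1 order:", co.order, "conflicts:", co.conflicting_bins)

# A noisier, hand-built bin string: the best-match sequence of a contig
# that crosses four B-contigs with a few mismapped bins.
tokens = (
    ["b1"] * 2 + ["b4"] * 3 + ["b1"] * 3 + ["b3"] * 3
    + ["b1"] + ["b3"] + ["b2"] * 3 + ["b3"]
)
ba = BinAssignment("A3", 10_000, tuple((t, 10_000) for t in tokens))
co = order_contigs(ba)
print("A3 order:", co.order, "support:", co.support,
      "conflicting bins:", co.conflicting_bins)
# 13 of 17 bins support the order (b4, b1, b3, b2); the other 4 bins
# conflict with every one-block-per-contig partition and are dropped.
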