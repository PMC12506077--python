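"""Select one ortholog per taxon per gene family and concatenate.

A taxon with several copies in a gene tree keeps the copy sitting in the
clade densest in its own minor clade (score = length x k-mer coverage
breaks ties); missing gene families are gap-filled, and columns that are
mostly gaps are masked.
"""

from phylocurate.concat import build_supermatrix, mask_gap_columns, select_ortholog
from phylocurate.tree_engine import GeneTree

tree = GeneTree.from_newick_string(
    "(((Op_me_S001_NODE_7_length_900_cov_12.5_OG6_000004:1,"
    "Op_me_S001_NODE_8_length_800_cov_10_OG6_000004:1):1,"
    "(Op_me_S002_c1_OG6_000004:1,Op_me_S003_c1_OG6_000004:1):1):1,"
    "Ba_pr_S008_c1_OG6_000004:1);"
)
pick = select_ortholog(tree, "Op_me_S001")
print(f"representative for Op_me_S001: {pick}")
# the 900 x 12.5 = 11250-scoring copy wins over the 800 x 10 = 8000 one

alignments = {
    "OG6_000004": {
        "Op_me_S001_NODE_7_length_900_cov_12.5_OG6_000004": "MKVA",
        "Op_me_S002_c1_OG6_000004": "MRVA",
        "Ba_pr_S008_c1_OG6_000004": "MKIA",
    },
    "OG6_000005": {
        "Op_me_S001_c1_OG6_000005": "MKV-LL",
        "Ba_pr_S008_c1_OG6_000005": "MKIALL",
    },
}
taxa = ["Op_me_S001", "Op_me_S002", "Ba_pr_S008"]
selected = {(gf, sid[:10]): sid for gf, aln in alignments.items() for sid in aln}
sm = build_supermatrix(alignments, taxa, selected)
print(f"\nsupermatrix: {len(sm.taxa)} taxa x {sm.width} columns")
print(f"partitions:  {sm.partitions}")
for taxon in sm.taxa:
    print(f"  {taxon}  {sm.rows[taxon]}")
# Op_me_S002 is absent from OG6_000005, so its row ends in six gaps

masked = mask_gap_columns(sm, 0.5)
print(f"\nafter masking columns with >=50% gaps: {masked.width} columns")
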