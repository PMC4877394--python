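"""Synteny blocks and the fate of missing genes between two genomes.

Shared genes are grouped into maximal runs that are consecutive and
co-oriented in both genomes.  A gene present in only one genome is a clean
internal excision when its flanking genes remain adjacent in the other
genome, and breakpoint-associated when the loss coincides with a
rearrangement breakpoint.
"""

from plastcomp import SignedGeneOrder, classify_missing_genes, synteny_blocks

A = SignedGeneOrder("algaA", [(g, 1, 1) for g in
                              ["psbA", "rbcL", "rps14", "petA", "atpB",
                               "ccsA", "ndhF", "psaA"]], "circular")
B = SignedGeneOrder("algaB", [("psbA", 1, 1), ("rbcL", 1, 1),
                              ("petA", 1, 1), ("atpB", 1, 1),
                              ("psaA", 1, -1), ("ndhF", 1, -1)], "circular")

blocks = synteny_blocks(A, B)
print(f"{blocks.n_common} shared genes fall into {blocks.n_blocks} blocks:")
for blk in blocks.blocks:
    print(f"  block {blk.block_id} ({blk.orientation}): "
          + " ".join(blk.genes))

records = classify_missing_genes(A, B, blocks)
for rec in records:
    print(f"{rec.gene} (only in {rec.donor}): {rec.classification}")
# rps14 sits between psbA..rbcL and petA..atpB, which stay adjacent in algaB:
# a clean excision; ccsA lies at a block boundary, so its loss coincides
# with a rearrangement breakpoint
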