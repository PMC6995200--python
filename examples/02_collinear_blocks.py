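"""Detect collinear blocks between two genomes.

Homologous pairs become anchors on the gene-order dotplot of each
chromosome pair; chains of anchors with gaps of at most 50 genes and at
least 4 members are collinear blocks.  Each block gets a median Ks and a
binomial significance against uniform anchor placement.
"""
from paleoploidy import carrot_like_config, detect_blocks, simulate_history

clade = simulate_history(carrot_like_config(seed=1, n_ancestral_genes=300))
pairs = clade.true_pairs.rename(columns={"true_ks": "ks"})

blocks = detect_blocks(clade.genomes["reference"], clade.genomes["target"], pairs)
print(f"{len(blocks)} blocks between reference and target\n")
for b in blocks[:8]:
    print(f"{b.chrom_a:14s} ~ {b.chrom_b:24s} {b.n_anchors:4d} anchors "
          f"median Ks {b.median_ks:.3f}  p={b.p_value:.2e}")

# Blocks with median Ks near 1.09 join regions separated by the speciation
# (orthologous); blocks near 1.22 join regions separated by the older shared
# hexaploidy (outparalogous) and carry fewer anchors after fractionation.
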