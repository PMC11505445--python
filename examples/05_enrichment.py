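"""Over-representation analysis of miRNA target genes.

Builds a toy validated miRNA→gene map and one GMT pathway collection in
memory, then tests which pathways are over-represented among the
targets of a set of "significant" miRNAs.
"""

from censq import map_targets, ora_test

target_map = {
    "miR-a": {"IL6", "TNF", "VEGFA"},
    "miR-b": {"VEGFA", "MMP9"},
    "miR-c": {"ESR1", "PGR"},
    "miR-d": {"CDK1"},
    "miR-e": {"ACTB"},
}
pathways = {
    "inflammation": ("cytokine signalling", {"IL6", "TNF", "IL1B"}),
    "angiogenesis": ("vessel growth", {"VEGFA", "MMP9", "FLT1"}),
    "hormone": ("estrogen/progesterone response", {"ESR1", "PGR", "GPER1"}),
}

significant = ["miR-a", "miR-b"]
query = map_targets(significant, target_map)
universe = set().union(*target_map.values())
print(f"query gene set: {sorted(query)} (universe size {len(universe)})")

table = ora_test(query, pathways, universe)
print(table.round(4).to_string(index=False))
# k of K pathway genes appear among the n query genes drawn from the
# N-gene universe; p is the hypergeometric upper tail, fdr the BH value.
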