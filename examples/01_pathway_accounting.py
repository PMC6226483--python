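"""Build a tiny pathway by hand and print its accounting summary.

Reactions are grouped into sub-metabolisms; the summary counts enzymes
(EC numbers), reaction types, genes, proteins and metabolites per
sub-metabolism and de-duplicates anything shared in the total row, so
the total can be smaller than the column sums.
"""

from pathrecon import PathwayDefinition, Reaction, summarize

pathway = PathwayDefinition(species="demo")
pathway.add_reaction(Reaction(
    "R00001", ec_numbers=frozenset({"2.7.1.1"}),
    substrates=frozenset({"glucose"}), products=frozenset({"G6P"}),
    sub_metabolisms=frozenset({"CAL", "SUC"}),  # shared by two sub-metabolisms
))
pathway.add_reaction(Reaction(
    "R00002", ec_numbers=frozenset({"5.3.1.9"}),
    substrates=frozenset({"G6P"}), products=frozenset({"F6P"}),
    sub_metabolisms=frozenset({"SUC"}),
))
pathway.add_reaction(Reaction(
    "R00003", ec_numbers=frozenset(), rtype="spontaneous",
    substrates=frozenset({"F6P"}), products=frozenset({"F6P-open"}),
    sub_metabolisms=frozenset({"SUC"}),
))
# two isozymes (different genes) plus one isoform pair (same gene)
pathway.ec_to_proteins["2.7.1.1"] = {"000001_000001", "000002_000002"}
pathway.ec_to_proteins["5.3.1.9"] = {"000003_000003", "000003_000004"}

summary = summarize(pathway)
print(summary.to_frame().to_string(index=False))
print()
print("R00001 sits in both CAL and SUC, so each row counts its EC once")
print("but the Total row de-duplicates: total ECs =", summary.total.n_ec)
print("Gene vs protein accounting: 000003_000003/000003_000004 share a gene,")
print("so", summary.total.n_proteins, "proteins map to", summary.total.n_genes, "genes.")
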