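"""Assemble a pre-pathway, detect gaps, and curate them.

Two templates contribute three reactions; only one enzyme is annotated,
so two reactions become gaps.  A curation record fills one gap from an
external database and the unaddressed gap is converted to an orphan
reaction (kept for connectivity, excluded from protein accounting).
"""

from pathrecon import CurationRecord, GapFill, PathwayDefinition, Reaction
from pathrecon.annotation import EnzymeAnnotation
from pathrecon.reconstruction import apply_curation, assemble_pre_pathway, detect_gaps

template = PathwayDefinition(species="template")
for rid, ec in [("R00010", "1.1.1.1"), ("R00011", "2.2.2.2"), ("R00012", "3.3.3.3")]:
    template.add_reaction(Reaction(rid, ec_numbers=frozenset({ec}),
                                   sub_metabolisms=frozenset({"AMI"})))

annotations = [EnzymeAnnotation("000001_000001", "1.1.1.1",
                                supporting_templates={"template"})]
pre = assemble_pre_pathway(annotations, {"template": template}, scope={"AMI"})
print("gaps detected:", detect_gaps(pre))

record = CurationRecord(filled_gaps=(
    GapFill("R00011", "2.2.2.2", proteins=("000900_000900", "000901_000901"),
            genes=("000900", "000901"), source_db_name="external-db"),
))
curated = apply_curation(pre, record)
for rid, r in sorted(curated.reactions.items()):
    print(f"{rid}: {r.rtype:10s} proteins={sorted(curated.reaction_proteins(rid))}")
print("R00011 was filled (2 proteins from the external database);")
print("R00012 had no fill and became an orphan; reaction count is unchanged.")
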