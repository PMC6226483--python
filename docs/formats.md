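# File formats

## Pathway JSON (lossless dialect)

One document per species:

```json
{
 "species": "arabidopsis",
 "reactions": [
  {
   "reaction_id": "R00199",
   "ec_numbers": ["2.7.9.2"],
   "substrates": ["pyruvate", "ATP"],
   "products": ["phosphoenolpyruvate", "AMP"],
   "sub_metabolisms": ["RES"],
   "rtype": "enzymatic"
  }
 ],
 "ec_to_proteins": {"2.7.9.2": ["000266_000266"]}
}
```

`rtype` is one of `enzymatic | spontaneous | gap | orphan`;
`sub_metabolisms` uses the codes `CAL SUC STA RES AMI CEL FAT NUC`;
`ec_to_proteins` may map ECs to empty lists (template species used only
as reaction references). Enzymatic reactions must carry ≥ 1 EC; gap and
orphan reactions must have no attached proteins.

## Pathway TSV (interchange dialect)

One row per reaction / sub-metabolism pair, header
`reaction_id  ec  sub_metabolism  rtype  substrates  products`,
with `ec`, `substrates` and `products` as semicolon-separated lists.
Carries the reaction catalogue only (no protein index).

## Annotation table TSV

`protein_id  ec  cs  ms  supporting_templates` with the supporter list
semicolon-separated.

## Alignment hits

BLAST tabular (outfmt 6) with the standard 12 columns, optionally
followed by a `qcovs` column; without it, query lengths must be
supplied so coverage can be computed from `qstart`/`qend`.

## Curation record YAML

```yaml
filled_gaps:
- reaction_id: R03013
  ec: 2.7.1.130
  proteins: [000910_000910, 000911_000911]
  genes: ["000910", "000911"]
  source_db_name: curation-db
  sub_metabolism: AMI
declared_orphans: [R04591]
```

## Evidence

- `clones.tsv`: `protein_id  ec  genbank_accession`.
- one `expr_<dataset>.tsv` per transcriptome dataset; the first column
  holds gene ids (or 12-digit protein ids, reduced to their gene part).

## Scenario bundle layout

```
bundle/
  query.faa            # query proteome
  templates/<k>.faa    # template proteomes
  pathways/<k>.json    # template pathway definitions
  curation.yaml
  evidence/clones.tsv
  evidence/expr_*.tsv
  truth.json           # planted ground truth
  manifest.yaml        # seed + full generator config
```
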