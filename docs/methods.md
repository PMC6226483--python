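# Methods

## Data model

A pathway is a set of `Reaction` records (stable string ids, KEGG-style
`Rxxxxx` or local), each carrying EC numbers, substrate/product
metabolite names, one or more sub-metabolism memberships, and a type:
`enzymatic`, `spontaneous`, `gap` (enzyme required but not annotated)
or `orphan` (biochemically characterised but gene unidentified).
Reaction identity across species is by id string match; no structural
substrate/product matching is attempted. A reaction shared by several
sub-metabolisms is stored once and expanded per row at summary time,
which is why per-row counts can sum to more than the de-duplicated
total.

Accounting (`summarize`) counts ECs, proteins and genes from enzymatic
and spontaneous reactions only: gap and orphan reactions are retained
for connectivity but contribute neither enzymes nor proteins. This is
what makes curation raise the EC total — each gap fill brings its
reaction's EC into the counted set — while the one surviving orphan's
EC stays uncounted. Gene accounting derives from the 12-digit protein
identifier convention `GGGGGG_PPPPPP`, where isoforms of one gene share
the gene part; identifiers not matching the pattern count as their own
gene.

`merge_counts_after_curation` applies a curation record at the summary
level. When the summary came from a real `PathwayDefinition` it carries
the underlying identifier sets and de-duplicates additions by set
union; when it was constructed from printed counts alone, additions are
de-duplicated within the record and assumed disjoint from the
pre-existing pathway.

## Alignment and annotation

The built-in aligner is Smith–Waterman (Biopython `PairwiseAligner`,
local mode) with BLOSUM62, gap open 11 / extend 1. Identity is
identities over aligned columns (gaps included); coverage is the
aligned span over the query length, measured on the query side of each
direction of the reciprocal search. E-values use the Karlin–Altschul
approximation E = m·n·K·e^(−λS) with the gapped BLOSUM62(11,1)
constants λ = 0.267, K = 0.041 and plain sequence lengths as the search
space — adequate for filtering at E ≤ 1e−10, not for edge-effect-exact
statistics. The backend is pluggable; a BLAST tabular (outfmt 6)
adapter ingests hits from an external BLASTp run on real data.

Filters default to E ≤ 1×10⁻¹⁰, identity ≥ 60, coverage ≥ 80, all
boundaries inclusive. Best hits are chosen by bit score, ties broken by
identity then lexicographic subject id, so results are deterministic.
A pair is reciprocal-best iff each side is the other's best *filtered*
hit. For speed, pairs are screened on the score-only E-value (a
function of raw score and lengths alone) before the costly traceback;
this cannot change the result because any pair failing the screen
would fail the E-value filter.

CS and MS are reimplementations of an operationally-defined confidence
protocol: CS is the supporter fraction m/N (so it only takes values
k/N), MS the best supporting bit score divided by the query
self-alignment bit score, clipped to [0, 1]. Proteins may hold one
annotation per EC (many-to-many enzyme/protein relations are expected).

## Reconstruction and curation

The pre-pathway is the union of template reactions within the
sub-metabolism scope (merged by id). Enzymatic reactions with at least
one EC and no annotated protein become gaps; an EC annotated anywhere
in scope rescues every reaction carrying it. Curation fills gaps
(proteins merged by id — re-applying a record is a no-op, giving
idempotence), validates that a fill's EC belongs to the target
reaction, and converts the remaining gaps to orphans by default; a
strict mode errors on unaddressed gaps instead. Curation never changes
the reaction count. Overlap with an external reference catalogue is
reported on both reactions and ECs, since the appropriate denominator
depends on the reference.

## Evidence validation

Clone evidence matches at protein level and requires exact EC equality
with an annotated EC. Expression evidence matches at gene level (gene
part of the protein id), so one expressed gene supports all its
isoforms. "Validated" is clone-supported OR expressed in ≥ 1 dataset;
"multi-dataset" means ≥ 2 distinct datasets. Reported percentages are
rounded half-up to integers with raw fractions retained; the
multi-dataset share is emitted against both plausible denominators
(expression-supported proteins, and all proteins), labelled, because
either convention is defensible.

## Comparative statistics

- **HD** is computed over the query's enzymatic reactions only
  (spontaneous, gap and orphan excluded); presence in the template is
  by reaction id anywhere in its definition. The measure is asymmetric
  by construction — template-only reactions are ignored. The overall
  row pools enzymatic reactions across sub-metabolisms de-duplicated,
  to avoid double-counting cross-listed reactions.
- **P score**: c_l counts a protein once per supporting species
  (supports are not partitioned or fractionally split), and d_j counts
  all ECs attached to sub-metabolism j including orphan ECs, which
  contribute 0 to the numerator. ECs with no annotated protein likewise
  contribute 0.
- **Complexity report**: per-EC C_P/E pooled over all templates,
  per-sub distributions and means, bucket counts (≤ 5 and > 10
  proteins), and carbohydrate vs non-carbohydrate group means computed
  two ways — pooled over the group's de-duplicated annotated ECs and as
  the unweighted mean of per-sub means — and labelled, because the two
  agree only when sub-metabolism EC counts are balanced.
- **Conserved core**: enzymatic reactions of the query present in every
  template, with their ECs and per-sub shares; ECs supported by exactly
  one species are listed as species-specific.
- **CS distributions**: per-protein (a multi-EC protein takes its
  maximum CS), with median and adjusted Fisher–Pearson skewness;
  "right-skewed" is reported above 0.5, otherwise "symmetric" —
  a reporting threshold chosen because the qualitative label is only
  meant to separate clearly asymmetric supporter distributions from
  balanced ones. Degenerate samples (n < 3 or zero variance) are
  labelled symmetric.

## Synthetic scenarios

The generator emulates the six-template study design at desk scale.
Defaults: six templates; 60 reactions over the eight sub-metabolisms
(CAL 8, SUC 6, STA 6, RES 10, AMI 12, CEL 5, FAT 6, NUC 7 — roughly
proportional to the real catalogue at ~1/4 scale); two spontaneous
reactions (CAL, NUC); four planted gaps (3 AMI, 1 NUC); per-template
shared fractions 0.8–1.0 with the first template at 1.0 (the
"well-annotated model plant"), which guarantees the union of templates
covers the catalogue and keeps every other template's planted
HD = 1 − f exact; a right-skewed supporter-count distribution
(P(1..6) = .25/.20/.18/.15/.12/.10) so conservation scores spread over
k/6; isoform counts 1–4 per EC with 25% gene reuse, giving more
proteins than genes; ortholog identities uniform in 75–95% (safely
above the 60% filter); sequence lengths 80–150; 30% random decoy
proteins per template proteome; 5% clone coverage with exact ECs; and
six expression datasets covering 70/60/50/50/40/30% of genes, whose
union supports most proteins.

Orthologs are made by substituting residues of a template "base"
sequence at distinct positions, uniformly over the 19 alternatives, no
indels — so identity alone controls filter outcomes and coverage stays
at 100 (an identity target is realized within ±2 points; sequences
under 10 residues are rejected). A template that catalogues an enzyme
without supporting the query carries no protein for it (a reaction
reference only), making planted supporter sets — hence CS — exact by
construction. Planted gap slots are reserved while the catalogue is
built (single fresh EC, single membership), so any configuration with
planted gaps ≤ enzymatic reactions per sub-metabolism is feasible for
every seed. All randomness flows through one seeded source; equal
configs produce byte-identical bundles.

What passing recovery tests show — and don't: with no-indel mutation,
uniform substitutions and unrelated decoys, the planted signal is
unambiguous, so precision = recall = 1 demonstrates the pipeline's
bookkeeping (filters, reciprocity, EC transfer, supporter accumulation,
gap logic) rather than annotation accuracy on real proteomes, where
domain shuffling, paralogy and partial hits blur the RBH signal.

## Numerical choices and limitations

- All score comparisons use exact floating arithmetic on rationals of
  small integers (counts over counts), so recovery assertions can
  demand exact equality.
- Percentages for prose-style reporting round half-up (ties away from
  zero), unlike Python's default banker's rounding.
- Problem sizes in tests: toy oracles use ≤ 10 reactions / ≤ 6 ECs over
  1,000 seeded trials; alignment-heavy tests use a reduced 26-reaction
  scenario; the acceptance script runs the full 60-reaction scenario.
- Out of scope: SBML/BioPAX exchange, stoichiometric/flux modelling,
  compartmentalisation, profile/HMM annotation, phylogenetics, and
  significance testing of HD/P differences.
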