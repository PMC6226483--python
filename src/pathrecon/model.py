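"""Core data model for metabolic pathways.

A pathway is a catalogue of biochemical reactions grouped into eight
sub-metabolisms of carbon assimilation (Calvin cycle, sucrose, starch,
respiration, amino acid, cell wall, fatty acid and nucleotide
biosynthesis).  Each enzymatic reaction is driven by one or more enzymes
identified by EC number; query proteins annotated to an EC number are
attached through the pathway's EC index.  Reactions whose required
enzymatic proteins could not be annotated are *gap* reactions; gaps that
survive curation are *orphan* reactions, kept for connectivity but
excluded from protein and gene accounting.

Two serialisation dialects are supported: a JSON document per species
(lossless, including the EC -> protein index) and a TSV dialect with one
row per reaction / sub-metabolism pair for spreadsheet interchange
(reaction catalogue only; the protein index is not representable).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SUB_METABOLISMS",
    "CARBOHYDRATE_RELATED",
    "RTYPES",
    "ECNumber",
    "ProteinID",
    "Reaction",
    "PathwayDefinition",
    "SummaryRow",
    "PathwaySummary",
    "GapFill",
    "CurationRecord",
    "PathwayValidationError",
    "is_valid_ec",
    "gene_of",
    "read_pathway",
    "write_pathway",
    "summarize",
    "merge_counts_after_curation",
]

#: The eight sub-metabolism codes of the carbon assimilation pathway.
SUB_METABOLISMS: tuple[str, ...] = (
    "CAL", "SUC", "STA", "RES", "AMI", "CEL", "FAT", "NUC",
)

#: Carbohydrate-related sub-metabolisms (the remaining three -- AMI, FAT,
#: NUC -- are the non-carbohydrate group).
CARBOHYDRATE_RELATED: frozenset[str] = frozenset({"STA", "CAL", "RES", "SUC", "CEL"})

#: Reaction types.  ``gap`` and ``orphan`` reactions carry EC numbers but
#: no annotated proteins.
RTYPES: tuple[str, ...] = ("enzymatic", "spontaneous", "gap", "orphan")

_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")
_PROTEIN_ID_RE = re.compile(r"^(\d{6})_(\d{6})$")

#: EC numbers are dotted 4-field classification strings ("2.7.9.2");
#: comparison is exact string equality.
ECNumber = str


class PathwayValidationError(ValueError):
    """A pathway definition or serialised record violates the schema."""


def is_valid_ec(code: str) -> bool:
    """True iff *code* is a dotted 4-field EC string such as ``2.7.9.2``
    (the last field may be ``-`` for a partially classified activity)."""
    return bool(_EC_RE.match(code))


@dataclass(frozen=True, order=True)
class ProteinID:
    """12-digit protein identifier ``GGGGGG_PPPPPP``.

    The gene part is shared by isoform proteins encoded by one gene, so
    gene-level accounting is derivable from protein identifiers.
    """

    gene_part: str
    protein_part: str

    def __post_init__(self) -> None:
        for part in (self.gene_part, self.protein_part):
            if not (len(part) == 6 and part.isdigit()):
                raise ValueError(f"protein id parts must be 6-digit codes, got {part!r}")

    @classmethod
    def parse(cls, text: str) -> "ProteinID":
        m = _PROTEIN_ID_RE.match(text)
        if not m:
            raise ValueError(f"not a 12-digit protein id: {text!r}")
        return cls(m.group(1), m.group(2))

    def __str__(self) -> str:
        return f"{self.gene_part}_{self.protein_part}"


def gene_of(protein_id: str) -> str:
    """Gene identifier for a protein identifier.

    For 12-digit ``GGGGGG_PPPPPP`` ids this is the gene part; any other
    identifier (e.g. curation-sourced or template protein names) is its
    own gene.
    """
    m = _PROTEIN_ID_RE.match(protein_id)
    return m.group(1) if m else protein_id


@dataclass(frozen=True)
class Reaction:
    """One catalogued biochemical reaction.

    Reaction identity across species is by ``reaction_id`` string match
    (KEGG-style ``Rxxxxx`` or local ids); a reaction may belong to more
    than one sub-metabolism and is stored once with the set of
    memberships.
    """

    reaction_id: str
    ec_numbers: frozenset[str] = frozenset()
    substrates: frozenset[str] = frozenset()
    products: frozenset[str] = frozenset()
    sub_metabolisms: frozenset[str] = frozenset()
    rtype: str = "enzymatic"

    def __post_init__(self) -> None:
        if self.rtype not in RTYPES:
            raise PathwayValidationError(
                f"{self.reaction_id}: unknown reaction type {self.rtype!r}"
            )
        if not self.sub_metabolisms:
            raise PathwayValidationError(
                f"{self.reaction_id}: reaction must belong to >=1 sub-metabolism"
            )
        unknown = set(self.sub_metabolisms) - set(SUB_METABOLISMS)
        if unknown:
            raise PathwayValidationError(
                f"{self.reaction_id}: unknown sub-metabolism {sorted(unknown)}"
            )
        if self.rtype == "enzymatic" and not self.ec_numbers:
            raise PathwayValidationError(
                f"{self.reaction_id}: enzymatic reaction requires >=1 EC number"
            )
        for ec in self.ec_numbers:
            if not is_valid_ec(ec):
                raise PathwayValidationError(
                    f"{self.reaction_id}: malformed EC number {ec!r}"
                )

    @property
    def metabolites(self) -> frozenset[str]:
        return self.substrates | self.products


@dataclass
class PathwayDefinition:
    """A species' pathway: reactions plus the EC -> annotated-protein index.

    ``ec_to_proteins`` maps every EC referenced by any reaction to the
    set of annotated protein identifiers (empty for template species
    used only as reaction references).
    """

    species: str
    reactions: dict[str, Reaction] = field(default_factory=dict)
    ec_to_proteins: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # Every reaction-referenced EC must appear in the index.
        for ec in self.all_ecs():
            self.ec_to_proteins.setdefault(ec, set())

    def validate(self) -> None:
        for ec, prots in self.ec_to_proteins.items():
            if not is_valid_ec(ec):
                raise PathwayValidationError(f"malformed EC in index: {ec!r}")
            if not isinstance(prots, set):
                raise PathwayValidationError(f"EC index for {ec} must be a set")
        for r in self.reactions.values():
            if r.rtype in ("gap", "orphan") and self.reaction_proteins(r.reaction_id):
                raise PathwayValidationError(
                    f"{r.reaction_id}: {r.rtype} reaction has annotated proteins"
                )

    # -- views -----------------------------------------------------------

    def all_ecs(self) -> set[str]:
        return {ec for r in self.reactions.values() for ec in r.ec_numbers}

    @property
    def metabolites(self) -> set[str]:
        return {m for r in self.reactions.values() for m in r.metabolites}

    def reactions_in(self, sub: str) -> list[Reaction]:
        return [r for r in self.reactions.values() if sub in r.sub_metabolisms]

    def reaction_proteins(self, reaction_id: str) -> set[str]:
        """Annotated proteins attached to a reaction through its ECs."""
        r = self.reactions[reaction_id]
        out: set[str] = set()
        for ec in r.ec_numbers:
            out |= self.ec_to_proteins.get(ec, set())
        return out

    def proteins_of_ec(self, ec: str) -> set[str]:
        return set(self.ec_to_proteins.get(ec, set()))

    def ecs_of_protein(self, protein_id: str) -> set[str]:
        return {ec for ec, prots in self.ec_to_proteins.items() if protein_id in prots}

    def subs_present(self) -> list[str]:
        present = {s for r in self.reactions.values() for s in r.sub_metabolisms}
        return [s for s in SUB_METABOLISMS if s in present]

    def add_reaction(self, r: Reaction) -> None:
        if r.reaction_id in self.reactions:
            raise PathwayValidationError(f"duplicate reaction id {r.reaction_id}")
        self.reactions[r.reaction_id] = r
        for ec in r.ec_numbers:
            self.ec_to_proteins.setdefault(ec, set())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayDefinition):
            return NotImplemented
        return (
            self.species == other.species
            and self.reactions == other.reactions
            and {k: v for k, v in self.ec_to_proteins.items()}
            == {k: v for k, v in other.ec_to_proteins.items()}
        )


# ---------------------------------------------------------------------------
# Serialisation


def _reaction_to_record(r: Reaction) -> dict:
    return {
        "reaction_id": r.reaction_id,
        "ec_numbers": sorted(r.ec_numbers),
        "substrates": sorted(r.substrates),
        "products": sorted(r.products),
        "sub_metabolisms": sorted(r.sub_metabolisms),
        "rtype": r.rtype,
    }


def _reaction_from_record(rec: Mapping, where: str) -> Reaction:
    try:
        return Reaction(
            reaction_id=str(rec["reaction_id"]),
            ec_numbers=frozenset(rec.get("ec_numbers", ())),
            substrates=frozenset(rec.get("substrates", ())),
            products=frozenset(rec.get("products", ())),
            sub_metabolisms=frozenset(rec.get("sub_metabolisms", ())),
            rtype=rec.get("rtype", "enzymatic"),
        )
    except (KeyError, PathwayValidationError, TypeError) as exc:
        raise PathwayValidationError(f"{where}: {exc}") from exc


def write_pathway(p: PathwayDefinition, path, dialect: str = "json") -> None:
    """Serialise a pathway (``json`` is lossless; ``tsv`` drops the
    protein index and is intended for reaction-catalogue interchange)."""
    if dialect == "json":
        doc = {
            "species": p.species,
            "reactions": [
                _reaction_to_record(p.reactions[rid]) for rid in sorted(p.reactions)
            ],
            "ec_to_proteins": {
                ec: sorted(prots) for ec, prots in sorted(p.ec_to_proteins.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    elif dialect == "tsv":
        rows = []
        for rid in sorted(p.reactions):
            r = p.reactions[rid]
            for sub in sorted(r.sub_metabolisms):
                rows.append(
                    {
                        "reaction_id": r.reaction_id,
                        "ec": ";".join(sorted(r.ec_numbers)),
                        "sub_metabolism": sub,
                        "rtype": r.rtype,
                        "substrates": ";".join(sorted(r.substrates)),
                        "products": ";".join(sorted(r.products)),
                    }
                )
        pd.DataFrame(
            rows,
            columns=["reaction_id", "ec", "sub_metabolism", "rtype", "substrates", "products"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_pathway(path, dialect: str = "json", species: str | None = None) -> PathwayDefinition:
    """Read and validate a pathway definition.

    Raises :class:`PathwayValidationError` with record context on schema
    violations (unknown sub-metabolism names, enzymatic reactions without
    EC numbers, duplicate reaction ids).
    """
    if dialect == "json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise PathwayValidationError(f"{path}: not valid JSON: {exc}") from exc
        p = PathwayDefinition(species=species or doc.get("species", "unknown"))
        for i, rec in enumerate(doc.get("reactions", [])):
            r = _reaction_from_record(rec, f"{path}: reactions[{i}]")
            p.add_reaction(r)
        for ec, prots in doc.get("ec_to_proteins", {}).items():
            if not is_valid_ec(ec):
                raise PathwayValidationError(f"{path}: malformed EC {ec!r} in index")
            p.ec_to_proteins.setdefault(ec, set()).update(prots)
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        p = PathwayDefinition(species=species or "unknown")
        grouped: dict[str, dict] = {}
        for i, row in df.iterrows():
            rid = row["reaction_id"]
            rec = grouped.setdefault(
                rid,
                {
                    "reaction_id": rid,
                    "ec_numbers": [x for x in row["ec"].split(";") if x],
                    "substrates": [x for x in row["substrates"].split(";") if x],
                    "products": [x for x in row["products"].split(";") if x],
                    "sub_metabolisms": [],
                    "rtype": row["rtype"],
                },
            )
            if rec["rtype"] != row["rtype"]:
                raise PathwayValidationError(
                    f"{path}: line {i + 2}: conflicting rtype for {rid}"
                )
            rec["sub_metabolisms"].append(row["sub_metabolism"])
        for rid, rec in grouped.items():
            if len(rec["sub_metabolisms"]) != len(set(rec["sub_metabolisms"])):
                raise PathwayValidationError(
                    f"{path}: duplicate reaction/sub-metabolism row for {rid}"
                )
            p.add_reaction(_reaction_from_record(rec, f"{path}: {rid}"))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    p.validate()
    return p


# ---------------------------------------------------------------------------
# Summaries (Table-1-style accounting)


@dataclass
class SummaryRow:
    """Counts for one sub-metabolism (or the de-duplicated total).

    When built by :func:`summarize` the underlying identifier sets are
    retained so later merges can de-duplicate by set union; rows built
    from printed counts alone carry ``None`` sets.
    """

    n_ec: int = 0
    n_enzymatic: int = 0
    n_spontaneous: int = 0
    n_gap: int = 0
    n_orphan: int = 0
    n_genes: int = 0
    n_proteins: int = 0
    n_metabolites: int = 0
    ecs: set[str] | None = None
    genes: set[str] | None = None
    proteins: set[str] | None = None
    metabolites: set[str] | None = None
    reaction_ids: set[str] | None = None

    @property
    def n_reactions_total(self) -> int:
        return self.n_enzymatic + self.n_spontaneous + self.n_gap + self.n_orphan

    def copy(self) -> "SummaryRow":
        return SummaryRow(
            n_ec=self.n_ec,
            n_enzymatic=self.n_enzymatic,
            n_spontaneous=self.n_spontaneous,
            n_gap=self.n_gap,
            n_orphan=self.n_orphan,
            n_genes=self.n_genes,
            n_proteins=self.n_proteins,
            n_metabolites=self.n_metabolites,
            ecs=None if self.ecs is None else set(self.ecs),
            genes=None if self.genes is None else set(self.genes),
            proteins=None if self.proteins is None else set(self.proteins),
            metabolites=None if self.metabolites is None else set(self.metabolites),
            reaction_ids=None if self.reaction_ids is None else set(self.reaction_ids),
        )


@dataclass
class PathwaySummary:
    """Per-sub-metabolism rows plus a de-duplicated total row.

    Reactions, ECs, genes, proteins and metabolites shared across
    sub-metabolisms contribute to every row they occur in but are
    counted once in the total, so ``total.n_x <= sum(row.n_x)`` with
    equality exactly when nothing is shared.
    """

    rows: dict[str, SummaryRow] = field(default_factory=dict)
    total: SummaryRow = field(default_factory=SummaryRow)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for name in [*self.rows, "Total"]:
            row = self.total if name == "Total" else self.rows[name]
            recs.append(
                {
                    "sub_metabolism": name,
                    "n_ec": row.n_ec,
                    "n_enzymatic": row.n_enzymatic,
                    "n_spontaneous": row.n_spontaneous,
                    "n_gap": row.n_gap,
                    "n_orphan": row.n_orphan,
                    "n_reactions_total": row.n_reactions_total,
                    "n_genes": row.n_genes,
                    "n_proteins": row.n_proteins,
                    "n_metabolites": row.n_metabolites,
                }
            )
        return pd.DataFrame(recs)

    def copy(self) -> "PathwaySummary":
        return PathwaySummary(
            rows={k: v.copy() for k, v in self.rows.items()}, total=self.total.copy()
        )


def _row_from_reactions(p: PathwayDefinition, reactions: Sequence[Reaction]) -> SummaryRow:
    # ECs / proteins / genes are accounted from enzymatic + spontaneous
    # reactions only: gap and orphan reactions are retained for
    # connectivity but contribute neither enzymes nor proteins.
    counted = [r for r in reactions if r.rtype in ("enzymatic", "spontaneous")]
    ecs = {ec for r in counted for ec in r.ec_numbers}
    proteins = {pid for ec in ecs for pid in p.ec_to_proteins.get(ec, set())}
    genes = {gene_of(pid) for pid in proteins}
    metabolites = {m for r in reactions for m in r.metabolites}
    return SummaryRow(
        n_ec=len(ecs),
        n_enzymatic=sum(r.rtype == "enzymatic" for r in reactions),
        n_spontaneous=sum(r.rtype == "spontaneous" for r in reactions),
        n_gap=sum(r.rtype == "gap" for r in reactions),
        n_orphan=sum(r.rtype == "orphan" for r in reactions),
        n_genes=len(genes),
        n_proteins=len(proteins),
        n_metabolites=len(metabolites),
        ecs=ecs,
        genes=genes,
        proteins=proteins,
        metabolites=metabolites,
        reaction_ids={r.reaction_id for r in reactions},
    )


def summarize(p: PathwayDefinition) -> PathwaySummary:
    """Table-1-style accounting: one row per sub-metabolism plus a
    de-duplicated total row."""
    rows = {
        sub: _row_from_reactions(p, p.reactions_in(sub)) for sub in p.subs_present()
    }
    total = _row_from_reactions(p, list(p.reactions.values()))
    return PathwaySummary(rows=rows, total=total)


# ---------------------------------------------------------------------------
# Curation records and summary-level merging


@dataclass(frozen=True)
class GapFill:
    """One curated gap: a reaction made enzymatic by externally sourced
    proteins/genes (e.g. from a species-specific pathway database)."""

    reaction_id: str
    ec: str
    proteins: tuple[str, ...]
    genes: tuple[str, ...]
    source_db_name: str = ""
    sub_metabolism: str | None = None  # required for summary-level merges

    def __post_init__(self) -> None:
        if not self.proteins or not self.genes:
            raise ValueError(f"fill for {self.reaction_id}: proteins/genes must be non-empty")
        if not is_valid_ec(self.ec):
            raise ValueError(f"fill for {self.reaction_id}: malformed EC {self.ec!r}")


@dataclass(frozen=True)
class CurationRecord:
    """Curation of a pre-pathway: gap fills plus explicitly declared
    orphans (unaddressed gaps default to orphan conversion)."""

    filled_gaps: tuple[GapFill, ...] = ()
    declared_orphans: tuple[str, ...] = ()


def merge_counts_after_curation(pre: PathwaySummary, record: CurationRecord) -> PathwaySummary:
    """Apply a curation record at the accounting level.

    Each filled gap becomes enzymatic; remaining gaps become orphans.
    Protein/gene/EC additions are de-duplicated: against the retained
    identifier sets when the summary came from :func:`summarize`, and
    within the record itself (assumed disjoint from the pre-existing
    pathway) when the summary was built from printed counts alone.
    """
    out = pre.copy()

    def _add(row: SummaryRow, attr: str, items: Iterable[str]) -> None:
        ids = getattr(row, attr)
        n_attr = {"ecs": "n_ec", "genes": "n_genes", "proteins": "n_proteins"}[attr]
        if ids is not None:
            before = len(ids)
            ids.update(items)
            setattr(row, n_attr, getattr(row, n_attr) + len(ids) - before)
        else:
            seen = row.__dict__.setdefault("_merged_" + attr, set())
            new = [x for x in items if x not in seen]
            seen.update(new)
            setattr(row, n_attr, getattr(row, n_attr) + len(new))

    for fill in record.filled_gaps:
        sub = fill.sub_metabolism
        if sub is None and pre.rows:
            for name, row in pre.rows.items():
                if row.reaction_ids and fill.reaction_id in row.reaction_ids:
                    sub = name
                    break
        if sub is None or sub not in out.rows:
            raise ValueError(
                f"fill for {fill.reaction_id}: sub-metabolism unknown or absent from summary"
            )
        row = out.rows[sub]
        if row.n_gap < 1:
            raise ValueError(f"fill for {fill.reaction_id}: no gap reactions left in {sub}")
        row.n_gap -= 1
        row.n_enzymatic += 1
        _add(row, "ecs", [fill.ec])
        _add(row, "proteins", fill.proteins)
        _add(row, "genes", fill.genes)
        out.total.n_gap -= 1
        out.total.n_enzymatic += 1
        _add(out.total, "ecs", [fill.ec])
        _add(out.total, "proteins", fill.proteins)
        _add(out.total, "genes", fill.genes)
    # Unfilled gaps are flagged orphan.
    for row in [*out.rows.values(), out.total]:
        row.n_orphan += row.n_gap
        row.n_gap = 0
        row.__dict__.pop("_merged_ecs", None)
        row.__dict__.pop("_merged_proteins", None)
        row.__dict__.pop("_merged_genes", None)
    return out
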