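"""Pre-pathway assembly, gap detection and curation.

The pre-pathway is assembled as the union of the template species'
reactions within the sub-metabolism scope; each reaction carries the
query proteins annotated to any of its ECs.  Enzymatic reactions whose
ECs attracted no annotation are flagged *gap*.  Curation then fills
gaps from an external source (proteins/genes merged by identifier) and
converts the remainder to *orphan* reactions — or, in strict mode,
raises instead.  Curation never changes the reaction count, only
reaction types and protein attachments.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable, Mapping

import yaml

from .annotation import EnzymeAnnotation
from .model import (
    CurationRecord,
    GapFill,
    PathwayDefinition,
    PathwayValidationError,
    Reaction,
)

__all__ = [
    "CurationRecord",
    "GapFill",
    "assemble_pre_pathway",
    "detect_gaps",
    "apply_curation",
    "curation_overlap",
    "read_curation_record",
    "write_curation_record",
]

logger = logging.getLogger(__name__)


def assemble_pre_pathway(
    annotations: Iterable[EnzymeAnnotation],
    templates: Mapping[str, PathwayDefinition],
    scope: set[str],
    species: str = "query",
) -> PathwayDefinition:
    """Union the template reactions in scope and attach annotations.

    Reactions occurring in several templates appear once (memberships,
    ECs and metabolites merged by reaction id).  Enzymatic reactions
    with at least one EC but no annotated protein are flagged ``gap``;
    spontaneous reactions pass through unflagged.
    """
    if not scope:
        raise ValueError("sub-metabolism scope must be non-empty")
    merged: dict[str, Reaction] = {}
    for t in templates.values():
        for r in t.reactions.values():
            if not (r.sub_metabolisms & scope):
                continue
            if r.reaction_id in merged:
                prev = merged[r.reaction_id]
                merged[r.reaction_id] = replace(
                    prev,
                    ec_numbers=prev.ec_numbers | r.ec_numbers,
                    substrates=prev.substrates | r.substrates,
                    products=prev.products | r.products,
                    sub_metabolisms=(prev.sub_metabolisms | r.sub_metabolisms) & scope,
                )
            else:
                merged[r.reaction_id] = replace(
                    r, sub_metabolisms=r.sub_metabolisms & scope
                )

    ec_index: dict[str, set[str]] = {}
    for a in annotations:
        ec_index.setdefault(a.ec, set()).add(a.protein)

    p = PathwayDefinition(species=species)
    for rid in sorted(merged):
        r = merged[rid]
        if r.rtype == "enzymatic" and not any(ec_index.get(ec) for ec in r.ec_numbers):
            r = replace(r, rtype="gap")
        p.add_reaction(r)
    for ec, prots in ec_index.items():
        if ec in p.ec_to_proteins:
            p.ec_to_proteins[ec] |= prots
        else:
            logger.debug("annotation EC %s is not attached to any reaction in scope", ec)
    p.validate()
    return p


def detect_gaps(p: PathwayDefinition) -> list[str]:
    """Sorted ids of enzyme-requiring reactions with no annotated
    protein for any of their ECs (an EC annotated elsewhere in scope
    rescues every reaction carrying it)."""
    return sorted(
        r.reaction_id
        for r in p.reactions.values()
        if r.rtype in ("enzymatic", "gap")
        and r.ec_numbers
        and not p.reaction_proteins(r.reaction_id)
    )


def apply_curation(
    pre: PathwayDefinition, rec: CurationRecord, strict: bool = False
) -> PathwayDefinition:
    """Fill gaps from a curation record and settle the remainder.

    Filled gaps become enzymatic with their proteins attached (merged by
    id, so re-applying the same record is a no-op).  Gaps listed in
    ``declared_orphans`` — and, by default, any unaddressed gap — become
    orphans; with ``strict=True`` unaddressed gaps raise instead.
    """
    out = PathwayDefinition(
        species=pre.species,
        reactions=dict(pre.reactions),
        ec_to_proteins={ec: set(v) for ec, v in pre.ec_to_proteins.items()},
    )
    for fill in rec.filled_gaps:
        if fill.reaction_id not in out.reactions:
            raise PathwayValidationError(f"fill references unknown reaction {fill.reaction_id}")
        r = out.reactions[fill.reaction_id]
        if fill.ec not in r.ec_numbers:
            raise PathwayValidationError(
                f"fill EC {fill.ec} contradicts reaction {fill.reaction_id} "
                f"(ECs: {sorted(r.ec_numbers)})"
            )
        already = set(fill.proteins) <= out.ec_to_proteins.get(fill.ec, set())
        if r.rtype != "gap" and not (r.rtype == "enzymatic" and already):
            raise PathwayValidationError(
                f"fill references non-gap reaction {fill.reaction_id} ({r.rtype})"
            )
        out.reactions[fill.reaction_id] = replace(r, rtype="enzymatic")
        out.ec_to_proteins.setdefault(fill.ec, set()).update(fill.proteins)
        logger.info(
            "gap %s -> enzymatic (+%d proteins, source %s)",
            fill.reaction_id, len(fill.proteins), fill.source_db_name or "n/a",
        )
    remaining = [r for r in out.reactions.values() if r.rtype == "gap"]
    declared = set(rec.declared_orphans)
    unknown = declared - set(out.reactions)
    if unknown:
        raise PathwayValidationError(f"declared orphans reference unknown reactions {sorted(unknown)}")
    for r in remaining:
        if strict and r.reaction_id not in declared:
            raise PathwayValidationError(
                f"strict mode: unaddressed gap reaction {r.reaction_id}"
            )
        out.reactions[r.reaction_id] = replace(r, rtype="orphan")
        logger.info("gap %s -> orphan", r.reaction_id)
    out.validate()
    return out


def curation_overlap(pre: PathwayDefinition, reference_reaction_ids: set[str]) -> dict:
    """Overlap of the pre-pathway with an external reference catalogue,
    reported on both reactions and ECs (the appropriate denominator for
    a given reference is a judgement call, so both are emitted)."""
    own = set(pre.reactions)
    shared = own & reference_reaction_ids
    own_ecs = pre.all_ecs()
    ref_ecs = {
        ec for rid in shared for ec in pre.reactions[rid].ec_numbers
    }
    return {
        "n_reactions": len(own),
        "n_reactions_shared": len(shared),
        "reaction_overlap_pct": 100.0 * len(shared) / len(own) if own else 0.0,
        "n_ecs": len(own_ecs),
        "n_ecs_shared": len(ref_ecs),
        "ec_overlap_pct": 100.0 * len(ref_ecs) / len(own_ecs) if own_ecs else 0.0,
    }


# ---------------------------------------------------------------------------
# Curation record I/O (YAML or JSON; YAML is a superset reader)


def write_curation_record(rec: CurationRecord, path) -> None:
    doc = {
        "filled_gaps": [
            {
                "reaction_id": f.reaction_id,
                "ec": f.ec,
                "proteins": list(f.proteins),
                "genes": list(f.genes),
                "source_db_name": f.source_db_name,
                **({"sub_metabolism": f.sub_metabolism} if f.sub_metabolism else {}),
            }
            for f in rec.filled_gaps
        ],
        "declared_orphans": list(rec.declared_orphans),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_curation_record(path) -> CurationRecord:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    fills = tuple(
        GapFill(
            reaction_id=f["reaction_id"],
            ec=f["ec"],
            proteins=tuple(f["proteins"]),
            genes=tuple(f["genes"]),
            source_db_name=f.get("source_db_name", ""),
            sub_metabolism=f.get("sub_metabolism"),
        )
        for f in doc.get("filled_gaps", [])
    )
    return CurationRecord(filled_gaps=fills, declared_orphans=tuple(doc.get("declared_orphans", [])))
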