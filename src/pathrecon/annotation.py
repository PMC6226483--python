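"""Reciprocal-best-hit ortholog annotation with confidence scores.

Query proteins inherit EC numbers from template species through
reciprocal best hits (RBH): a query/template pair is accepted when each
protein is the other's top-scoring hit after filtering on E-value,
percent identity and query coverage (defaults E <= 1e-10, identity >=
60, coverage >= 80, all boundaries inclusive).  Every annotation carries

* a conservation score CS = (number of supporting template species) /
  (number of templates), in [0, 1], and
* a match score MS = best supporting bit score divided by the query's
  self-alignment bit score, clipped to [0, 1]; MS = 1 means the
  ortholog matches as well as the query matches itself.

Both scores are supporter-fraction / self-normalised-ratio
reimplementations: the confidence-scoring protocol this follows defines
them only operationally, so the formulas here are this package's own
documented choices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .align import AlignmentHit, AlignParams, PairwiseBackend
from .model import PathwayDefinition

__all__ = [
    "Thresholds",
    "ReciprocalPair",
    "EnzymeAnnotation",
    "passes_filters",
    "reciprocal_best_hits",
    "annotate",
    "conservation_score",
    "match_score",
    "read_proteome",
    "write_annotation_table",
    "read_annotation_table",
]

logger = logging.getLogger(__name__)

#: A proteome is a mapping protein id -> amino-acid sequence.
Proteome = dict[str, str]


@dataclass(frozen=True)
class Thresholds:
    """Alignment acceptance filters (all boundaries inclusive)."""

    evalue: float = 1e-10
    identity: float = 60.0
    coverage: float = 80.0


@dataclass(frozen=True)
class ReciprocalPair:
    """A reciprocal best hit between a query and a template protein.

    ``forward`` holds the query-side statistics (coverage on the query),
    ``reverse`` the template-side statistics.
    """

    query_id: str
    subject_id: str
    forward: AlignmentHit
    reverse: AlignmentHit


@dataclass
class EnzymeAnnotation:
    """A query protein annotated to one EC number.

    One annotation exists per (protein, EC) pair; ``supporting_templates``
    accumulates every template species whose RBH partner carries the EC.
    """

    protein: str
    ec: str
    supporting_templates: set[str] = field(default_factory=set)
    cs: float = 0.0
    ms: float | None = None
    per_template_hits: dict[str, AlignmentHit] = field(default_factory=dict)
    self_bitscore: float | None = None


def passes_filters(h: AlignmentHit, t: Thresholds) -> bool:
    """True iff the hit meets all three criteria, boundaries inclusive."""
    return (
        h.evalue <= t.evalue
        and h.identity_pct >= t.identity
        and h.coverage_pct >= t.coverage
    )


def _best_hit(hits: list[AlignmentHit]) -> AlignmentHit | None:
    """Highest bit score; ties broken by higher identity, then
    lexicographically smaller subject id (determinism)."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.bitscore, -h.identity_pct, h.subject_id))


def reciprocal_best_hits(
    query: Proteome,
    template: Proteome,
    t: Thresholds | None = None,
    params: AlignParams | None = None,
) -> set[ReciprocalPair]:
    """All reciprocal best hits between two proteomes.

    Candidate pairs are first screened on the score-only E-value (which
    depends only on the raw alignment score and the sequence lengths),
    then full alignments provide identity and per-side coverage for the
    filters.  A pair (q, s) is accepted iff s is q's best filtered hit
    in the template and q is s's best filtered hit in the query.
    """
    if not query or not template:
        raise ValueError("both proteomes must be non-empty")
    t = t or Thresholds()
    backend = PairwiseBackend(params)

    fwd: dict[str, list[AlignmentHit]] = {q: [] for q in query}
    rev: dict[str, list[AlignmentHit]] = {s: [] for s in template}
    pair_hits: dict[tuple[str, str], tuple[AlignmentHit, AlignmentHit]] = {}
    for qid, qseq in query.items():
        for sid, sseq in template.items():
            raw = backend.score(qseq, sseq)
            if raw <= 0:
                continue
            # Score-only E-value screen before the costly traceback.
            if backend.evalue(raw, len(qseq), len(sseq)) > t.evalue:
                continue
            f = backend.align(qseq, sseq, qid, sid)
            r = backend.align(sseq, qseq, sid, qid)
            if f is None or r is None:
                continue
            if passes_filters(f, t) and passes_filters(r, t):
                fwd[qid].append(f)
                rev[sid].append(r)
                pair_hits[(qid, sid)] = (f, r)

    out: set[ReciprocalPair] = set()
    for qid, hits in fwd.items():
        best_f = _best_hit(hits)
        if best_f is None:
            continue
        best_r = _best_hit(rev[best_f.subject_id])
        if best_r is not None and best_r.subject_id == qid:
            f, r = pair_hits[(qid, best_f.subject_id)]
            out.add(ReciprocalPair(qid, best_f.subject_id, f, r))
    return out


def annotate(
    pairs_by_template: Mapping[str, Iterable[ReciprocalPair]],
    templates: Mapping[str, PathwayDefinition],
    self_bitscores: Mapping[str, float] | None = None,
) -> list[EnzymeAnnotation]:
    """Transfer EC numbers to query proteins through RBH partners.

    A query protein inherits EC ``e`` from template species ``k`` iff it
    is an RBH partner of a template protein assigned ``e`` in ``k``'s
    pathway.  Template proteins without any EC contribute nothing (a
    debug message is logged).  CS is filled from the supporter counts;
    MS is filled when query self-alignment bit scores are supplied.
    """
    n_templates = len(templates)
    if n_templates == 0:
        raise ValueError("at least one template pathway is required")
    by_key: dict[tuple[str, str], EnzymeAnnotation] = {}
    for species, pairs in pairs_by_template.items():
        pathway = templates[species]
        for pair in pairs:
            ecs = pathway.ecs_of_protein(pair.subject_id)
            if not ecs:
                logger.debug(
                    "template protein %s (%s) has no EC in its pathway; skipped",
                    pair.subject_id, species,
                )
                continue
            for ec in ecs:
                ann = by_key.setdefault(
                    (pair.query_id, ec), EnzymeAnnotation(protein=pair.query_id, ec=ec)
                )
                ann.supporting_templates.add(species)
                ann.per_template_hits[species] = pair.forward
    annotations = sorted(by_key.values(), key=lambda a: (a.protein, a.ec))
    for ann in annotations:
        ann.cs = conservation_score(ann, n_templates)
        if self_bitscores is not None:
            ann.self_bitscore = self_bitscores[ann.protein]
            ann.ms = match_score(ann)
    return annotations


def conservation_score(a: EnzymeAnnotation, n_templates: int) -> float:
    """Fraction of template species supporting the annotation."""
    if n_templates <= 0:
        raise ValueError("n_templates must be positive")
    if not a.supporting_templates:
        raise ValueError("annotation has no supporting templates")
    return len(a.supporting_templates) / n_templates


def match_score(a: EnzymeAnnotation) -> float:
    """Best supporting bit score over the query self-alignment bit
    score, clipped to [0, 1]."""
    if not a.per_template_hits:
        raise ValueError("annotation has no per-template hits")
    if not a.self_bitscore:
        raise ValueError("query self-alignment bit score is zero or unset")
    ratio = max(h.bitscore for h in a.per_template_hits.values()) / a.self_bitscore
    return min(1.0, max(0.0, ratio))


# ---------------------------------------------------------------------------
# I/O


def read_proteome(path) -> Proteome:
    """Read a protein FASTA; the first whitespace-delimited header token
    is the protein identifier."""
    proteome: Proteome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteome:
            raise ValueError(f"{path}: duplicate protein id {rec.id}")
        proteome[rec.id] = str(rec.seq)
    if not proteome:
        raise ValueError(f"{path}: no FASTA records")
    return proteome


def write_annotation_table(annotations: Iterable[EnzymeAnnotation], path) -> None:
    rows = [
        {
            "protein_id": a.protein,
            "ec": a.ec,
            "cs": round(a.cs, 6),
            "ms": "" if a.ms is None else round(a.ms, 6),
            "supporting_templates": ";".join(sorted(a.supporting_templates)),
        }
        for a in annotations
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "ec", "cs", "ms", "supporting_templates"]
    ).to_csv(path, sep="\t", index=False)


def read_annotation_table(path) -> list[EnzymeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "ec": str})
    out = []
    for row in df.itertuples():
        supporters = set(str(row.supporting_templates).split(";")) if row.supporting_templates else set()
        out.append(
            EnzymeAnnotation(
                protein=row.protein_id,
                ec=row.ec,
                supporting_templates=supporters,
                cs=float(row.cs),
                ms=None if pd.isna(row.ms) else float(row.ms),
            )
        )
    return out
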