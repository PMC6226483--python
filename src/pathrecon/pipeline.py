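"""End-to-end orchestration: annotate -> assemble -> curate -> validate
-> analyze.

This is the library-level composition of the stage functions; the CLI
wraps it stage by stage, and tests/recovery checks run it in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import comparative
from .align import AlignParams, PairwiseBackend
from .annotation import (
    EnzymeAnnotation,
    Proteome,
    ReciprocalPair,
    Thresholds,
    annotate,
    reciprocal_best_hits,
)
from .model import PathwayDefinition, PathwaySummary, summarize
from .reconstruction import apply_curation, assemble_pre_pathway, detect_gaps
from .synthetic import Scenario
from .validation import EvidenceOverlay, apply_evidence, support_summary

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Artifacts of one full reconstruction/analysis run."""

    pairs_by_template: dict[str, set[ReciprocalPair]]
    annotations: list[EnzymeAnnotation]
    pre_pathway: PathwayDefinition
    gaps: list[str]
    pathway: PathwayDefinition
    summary: PathwaySummary
    overlay: EvidenceOverlay | None = None
    support: pd.DataFrame | None = None
    hd: pd.DataFrame | None = None
    p_scores: pd.DataFrame | None = None
    complexity: dict = field(default_factory=dict)
    core: dict = field(default_factory=dict)


def run_pipeline(
    scenario: Scenario,
    thresholds: Thresholds | None = None,
    params: AlignParams | None = None,
    strict_curation: bool = False,
) -> PipelineResult:
    """Run the full workflow on an in-memory scenario bundle."""
    thresholds = thresholds or Thresholds()
    pairs_by_template = {
        k: reciprocal_best_hits(scenario.query_proteome, proteome, thresholds, params)
        for k, proteome in scenario.template_proteomes.items()
    }
    backend = PairwiseBackend(params)
    self_scores = {
        pid: backend.bitscore(backend.score(seq, seq))
        for pid, seq in scenario.query_proteome.items()
    }
    annotations = annotate(pairs_by_template, scenario.template_pathways, self_scores)
    pre = assemble_pre_pathway(annotations, scenario.template_pathways, scenario.scope)
    gaps = detect_gaps(pre)
    pathway = apply_curation(pre, scenario.curation, strict=strict_curation)
    summary = summarize(pathway)
    overlay = apply_evidence(pathway, scenario.clones, scenario.expression)
    support = support_summary(overlay, pathway)
    hd = comparative.hd_matrix(pathway, scenario.template_pathways)
    table = comparative.build_complexity_table(
        annotations, pathway, species=list(scenario.template_pathways)
    )
    p_scores = comparative.p_score_matrix(
        table, pathway.subs_present(), list(scenario.template_pathways)
    )
    return PipelineResult(
        pairs_by_template=pairs_by_template,
        annotations=annotations,
        pre_pathway=pre,
        gaps=gaps,
        pathway=pathway,
        summary=summary,
        overlay=overlay,
        support=support,
        hd=hd,
        p_scores=p_scores,
        complexity=comparative.complexity_report(table, pathway),
        core=comparative.conserved_core(pathway, scenario.template_pathways, annotations),
    )
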