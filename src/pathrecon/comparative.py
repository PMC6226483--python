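"""Comparative network statistics for reconstructed pathways.

Given a query pathway with enzyme annotations and the template species'
pathway definitions, this module computes the comparative measures used
to contrast pathway topology and enzymatic complexity across species:

* **Normalized Hamming distance** HD_j^k = (sum_i a_i) / b_j, where a_i
  is 0 when enzymatic reaction i of the query's sub-metabolism j also
  occurs in template k and 1 otherwise, and b_j is the number of
  enzymatic reactions in j.  HD is 0 for identical reaction complements
  and 1 for disjoint ones, and is asymmetric by construction: reactions
  present only in the template are ignored.
* **Complexity** C_P/E per enzyme: the number of query proteins
  annotated to one EC number pooled over all templates (isozyme /
  subunit complexity).
* **P score** P_j^k = (sum_l c_l / C_P/E,l) / d_j, where c_l counts the
  query proteins of EC l (in sub-metabolism j) whose annotation is
  supported by species k, and d_j is the number of ECs attached to
  pathway j (orphan ECs included; they contribute 0 to the numerator).
* **Conserved core**: reactions (and their ECs) present in the query
  and every template; plus species-specific annotations.
* **CS distributions**: per-sub-metabolism conservation-score
  histograms with median and a skewness label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .annotation import EnzymeAnnotation
from .model import CARBOHYDRATE_RELATED, PathwayDefinition

__all__ = [
    "CoexistenceMatrix",
    "ComplexityTable",
    "coexistence",
    "overall_coexistence",
    "hamming_distance",
    "hd_matrix",
    "build_complexity_table",
    "p_score",
    "p_score_matrix",
    "complexity_report",
    "enzyme_reaction_graph",
    "conserved_core",
    "cs_distribution",
    "scores_to_long",
]


@dataclass(frozen=True)
class CoexistenceMatrix:
    """Co-existence flags between one query sub-metabolism and one
    template: a[i] = 0 when reaction i occurs in both species."""

    sub_metabolism: str
    template: str
    a: tuple[tuple[str, int], ...]  # (reaction_id, flag) pairs, sorted

    @property
    def b(self) -> int:
        return len(self.a)


def _enzymatic_ids(p: PathwayDefinition, sub: str | None = None) -> list[str]:
    rs = p.reactions.values() if sub is None else p.reactions_in(sub)
    return sorted(r.reaction_id for r in rs if r.rtype == "enzymatic")


def coexistence(
    query: PathwayDefinition, template: PathwayDefinition, j: str
) -> CoexistenceMatrix:
    """Per-reaction co-existence flags for sub-metabolism *j*.

    The universe is the query's enzymatic reactions of j (spontaneous,
    gap and orphan reactions excluded); presence in the template is by
    reaction id anywhere in the template definition.
    """
    ids = _enzymatic_ids(query, j)
    if not ids:
        raise ValueError(f"sub-metabolism {j} has no enzymatic reactions in the query")
    return CoexistenceMatrix(
        sub_metabolism=j,
        template=template.species,
        a=tuple((rid, 0 if rid in template.reactions else 1) for rid in ids),
    )


def overall_coexistence(
    query: PathwayDefinition, template: PathwayDefinition
) -> CoexistenceMatrix:
    """Whole-pathway co-existence, pooling enzymatic reactions across
    sub-metabolisms with reactions shared by several sub-metabolisms
    counted once."""
    ids = _enzymatic_ids(query)
    if not ids:
        raise ValueError("query pathway has no enzymatic reactions")
    return CoexistenceMatrix(
        sub_metabolism="overall",
        template=template.species,
        a=tuple((rid, 0 if rid in template.reactions else 1) for rid in ids),
    )


def hamming_distance(m: CoexistenceMatrix) -> float:
    """Normalized Hamming distance sum(a_i)/b_j, in [0, 1]."""
    if m.b == 0:
        raise ZeroDivisionError("no enzymatic reactions to compare")
    return sum(flag for _, flag in m.a) / m.b


def hd_matrix(
    query: PathwayDefinition, templates: Mapping[str, PathwayDefinition]
) -> pd.DataFrame:
    """HD per (sub-metabolism, template), with an ``overall`` row
    pooling de-duplicated enzymatic reactions."""
    rows = {}
    for j in query.subs_present():
        if not _enzymatic_ids(query, j):
            continue
        rows[j] = {
            k: hamming_distance(coexistence(query, t, j)) for k, t in templates.items()
        }
    rows["overall"] = {
        k: hamming_distance(overall_coexistence(query, t)) for k, t in templates.items()
    }
    return pd.DataFrame(rows).T[list(templates)]


# ---------------------------------------------------------------------------
# Complexity and P score


@dataclass
class ComplexityTable:
    """Protein-per-enzyme complexity bookkeeping.

    ``c_pe[l]`` is the number of query proteins annotated to EC l pooled
    over all template species; ``c_by_species[(l, k)]`` the number of
    those proteins whose annotation is supported by species k (a protein
    supported by several species counts once for each); ``d[j]`` the
    number of ECs attached to sub-metabolism j, orphan ECs included;
    ``ecs_by_sub[j]`` those ECs.
    """

    c_pe: dict[str, int] = field(default_factory=dict)
    c_by_species: dict[tuple[str, str], int] = field(default_factory=dict)
    ecs_by_sub: dict[str, set[str]] = field(default_factory=dict)
    species: list[str] = field(default_factory=list)

    def d(self, j: str) -> int:
        return len(self.ecs_by_sub.get(j, set()))


def build_complexity_table(
    annotations: Iterable[EnzymeAnnotation],
    p: PathwayDefinition,
    species: Sequence[str] | None = None,
) -> ComplexityTable:
    anns = list(annotations)
    table = ComplexityTable(
        species=sorted(species or {s for a in anns for s in a.supporting_templates})
    )
    for j in p.subs_present():
        table.ecs_by_sub[j] = {ec for r in p.reactions_in(j) for ec in r.ec_numbers}
    for a in anns:
        table.c_pe[a.ec] = table.c_pe.get(a.ec, 0) + 1
        for k in a.supporting_templates:
            key = (a.ec, k)
            table.c_by_species[key] = table.c_by_species.get(key, 0) + 1
    return table


def p_score(c: ComplexityTable, j: str, k: str) -> float:
    """Mean, over the ECs of sub-metabolism j, of the fraction of each
    EC's annotated proteins supported by species k; ECs with no
    annotated protein contribute 0."""
    d = c.d(j)
    if d == 0:
        raise ZeroDivisionError(f"sub-metabolism {j} has no ECs")
    total = 0.0
    for ec in c.ecs_by_sub[j]:
        cpe = c.c_pe.get(ec, 0)
        if cpe:
            total += c.c_by_species.get((ec, k), 0) / cpe
    return total / d


def p_score_matrix(
    c: ComplexityTable, subs: Sequence[str], species: Sequence[str] | None = None
) -> pd.DataFrame:
    species = list(species or c.species)
    return pd.DataFrame(
        {j: {k: p_score(c, j, k) for k in species} for j in subs if c.d(j)}
    ).T[species]


def complexity_report(c: ComplexityTable, p: PathwayDefinition) -> dict:
    """Distribution of C_P/E per sub-metabolism and complexity-group
    means.

    Group means for the carbohydrate-related vs non-carbohydrate
    sub-metabolisms are computed two ways — pooled over each group's
    (de-duplicated) annotated ECs, and as the unweighted mean of the
    per-sub-metabolism means — and labelled; the two agree only when
    sub-metabolism EC counts are balanced.
    """
    per_sub: dict[str, list[int]] = {}
    for j, ecs in c.ecs_by_sub.items():
        per_sub[j] = sorted(c.c_pe[ec] for ec in ecs if ec in c.c_pe)
    annotated = sorted(c.c_pe.values())
    n_ec = len(annotated)

    def _group(subs: set[str]) -> dict:
        ecs = {ec for j in subs for ec in c.ecs_by_sub.get(j, set()) if ec in c.c_pe}
        pooled = [c.c_pe[ec] for ec in ecs]
        sub_means = [float(np.mean(per_sub[j])) for j in subs if per_sub.get(j)]
        return {
            "mean_pooled_ecs": float(np.mean(pooled)) if pooled else 0.0,
            "mean_of_sub_means": float(np.mean(sub_means)) if sub_means else 0.0,
            "n_ecs": len(ecs),
        }

    subs_present = set(c.ecs_by_sub)
    return {
        "per_ec": dict(sorted(c.c_pe.items())),
        "per_sub_values": per_sub,
        "per_sub_mean": {
            j: float(np.mean(v)) if v else 0.0 for j, v in per_sub.items()
        },
        "n_annotated_ecs": n_ec,
        "n_le5": sum(v <= 5 for v in annotated),
        "n_gt10": sum(v > 10 for v in annotated),
        "share_le5_pct": 100.0 * sum(v <= 5 for v in annotated) / n_ec if n_ec else 0.0,
        "share_gt10_pct": 100.0 * sum(v > 10 for v in annotated) / n_ec if n_ec else 0.0,
        "max_c_pe": max(annotated) if annotated else 0,
        "carbohydrate_group": _group(subs_present & CARBOHYDRATE_RELATED),
        "non_carbohydrate_group": _group(subs_present - CARBOHYDRATE_RELATED),
    }


# ---------------------------------------------------------------------------
# Enzyme-reaction bipartite structure


def enzyme_reaction_graph(p: PathwayDefinition) -> dict:
    """Bipartite EC / reaction graph with relation classes.

    Nodes are EC numbers (bipartite=0) and reaction ids (bipartite=1);
    an edge joins an EC to every reaction it drives.  The report lists
    per-EC degree, multi-reaction ECs (degree >= 2), ECs spanning more
    than one sub-metabolism (*cross-pathway*), and a relation class per
    EC: ``1:1`` (one EC, one reaction, no partner enzymes), ``1:many``
    (one EC driving several reactions), ``many:1`` (EC sharing its only
    reaction with other ECs), and ``cross-pathway``.
    """
    g = nx.Graph()
    for r in p.reactions.values():
        g.add_node(r.reaction_id, bipartite=1, rtype=r.rtype)
        for ec in r.ec_numbers:
            g.add_node(ec, bipartite=0)
            g.add_edge(ec, r.reaction_id)
    ec_nodes = sorted(n for n, d in g.nodes(data=True) if d["bipartite"] == 0)
    degree = {ec: g.degree(ec) for ec in ec_nodes}
    subs_of_ec = {
        ec: {s for rid in g.neighbors(ec) for s in p.reactions[rid].sub_metabolisms}
        for ec in ec_nodes
    }
    classes = {}
    for ec in ec_nodes:
        if len(subs_of_ec[ec]) > 1:
            classes[ec] = "cross-pathway"
        elif degree[ec] >= 2:
            classes[ec] = "1:many"
        elif any(len(p.reactions[rid].ec_numbers) > 1 for rid in g.neighbors(ec)):
            classes[ec] = "many:1"
        else:
            classes[ec] = "1:1"
    multi = sorted(ec for ec in ec_nodes if degree[ec] >= 2)
    return {
        "graph": g,
        "n_ecs": len(ec_nodes),
        "degree": degree,
        "multi_reaction_ecs": multi,
        "multi_reaction_share_pct": 100.0 * len(multi) / len(ec_nodes) if ec_nodes else 0.0,
        "cross_pathway_ecs": sorted(ec for ec in ec_nodes if len(subs_of_ec[ec]) > 1),
        "relation_class": classes,
    }


# ---------------------------------------------------------------------------
# Conserved core and CS distributions


def conserved_core(
    query: PathwayDefinition,
    templates: Mapping[str, PathwayDefinition],
    annotations: Iterable[EnzymeAnnotation] | None = None,
) -> dict:
    """Reactions and ECs present in the query and all templates.

    The universe is the query's enzymatic reactions.  When annotations
    are supplied, ECs supported by exactly one species are listed as
    species-specific (with that species).
    """
    if not templates:
        raise ValueError("at least one template is required")
    ids = _enzymatic_ids(query)
    core = [
        rid for rid in ids if all(rid in t.reactions for t in templates.values())
    ]
    core_ecs = sorted({ec for rid in core for ec in query.reactions[rid].ec_numbers})
    per_sub = {}
    for j in query.subs_present():
        sub_ids = set(_enzymatic_ids(query, j))
        if not sub_ids:
            continue
        in_core = sub_ids & set(core)
        per_sub[j] = {
            "n_enzymatic": len(sub_ids),
            "n_core": len(in_core),
            "core_pct": 100.0 * len(in_core) / len(sub_ids),
        }
    out = {
        "n_enzymatic": len(ids),
        "core_reactions": core,
        "n_core_reactions": len(core),
        "core_share_pct": 100.0 * len(core) / len(ids) if ids else 0.0,
        "core_ecs": core_ecs,
        "n_core_ecs": len(core_ecs),
        "per_sub": per_sub,
    }
    if annotations is not None:
        out["species_specific"] = sorted(
            (a.ec, next(iter(a.supporting_templates)))
            for a in annotations
            if len(a.supporting_templates) == 1
        )
    return out


def cs_distribution(
    annotations: Iterable[EnzymeAnnotation],
    j: str,
    p: PathwayDefinition,
) -> dict:
    """Conservation-score distribution of the proteins of
    sub-metabolism *j*.

    A protein belongs to j when any of its annotated ECs is attached to
    a reaction of j; a multi-EC protein's CS is the maximum over its
    annotations.  Skewness is the adjusted Fisher-Pearson moment
    coefficient; distributions with skewness > 0.5 are labelled
    right-skewed, otherwise symmetric (degenerate samples are
    symmetric by convention).
    """
    sub_ecs = {ec for r in p.reactions_in(j) for ec in r.ec_numbers}
    per_protein: dict[str, float] = {}
    for a in annotations:
        if a.ec in sub_ecs:
            per_protein[a.protein] = max(per_protein.get(a.protein, 0.0), a.cs)
    if not per_protein:
        raise ValueError(f"no annotations fall in sub-metabolism {j}")
    values = np.array(sorted(per_protein.values()))
    if len(values) >= 3 and values.std() > 0:
        skew = float(stats.skew(values, bias=False))
    else:
        skew = 0.0
    hist: dict[float, int] = {}
    for v in values:
        hist[round(float(v), 6)] = hist.get(round(float(v), 6), 0) + 1
    return {
        "n_proteins": len(values),
        "histogram": dict(sorted(hist.items())),
        "median": float(np.median(values)),
        "skewness": skew,
        "shape": "right-skewed" if skew > 0.5 else "symmetric",
    }


def scores_to_long(matrix: pd.DataFrame, score_name: str) -> pd.DataFrame:
    """Wide score matrix (rows sub-metabolisms, columns templates) to
    heatmap-ready long format."""
    long = matrix.reset_index(names="sub_metabolism").melt(
        id_vars="sub_metabolism", var_name="template", value_name=score_name
    )
    return long.sort_values(["sub_metabolism", "template"]).reset_index(drop=True)
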